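"""Crystal-ensemble comparison: ligand classification, RMSD partitioning and
enrichment statistics.

Reference ("crystal") loop conformations are classified as nucleotide-bound
if any of their ligand residue names is on the recognized 14-entry
nucleotide/analogue list, partitioned by backbone RMSD to a reference
conformation (within / beyond 0.6 Å; conformations the crystal ensemble
rarely leaves), and cross-tabulated.  Enrichment is quantified with an
in-package two-sided Fisher exact test (hypergeometric terms in log space,
probability-mass rule) plus bootstrap confidence intervals on the cell
fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .featurize import Structure, superpose_rmsd

#: residue names recognized as nucleotides or nucleotide analogues
NUCLEOTIDE_RESNAMES = frozenset({
    "ADP", "ATP", "ANP", "MNQ", "MNT", "ONP", "PNQ",
    "DAE", "DAQ", "NMQ", "AGS", "AD9", "AOV", "FLC",
})


def classify_ligand(ligand_names) -> bool:
    """True iff any (upper-cased, stripped) name is a recognized nucleotide
    or nucleotide analogue."""
    return any(str(n).strip().upper() in NUCLEOTIDE_RESNAMES for n in ligand_names)


@dataclass
class CrystalRecord:
    """One reference structure: loop fragment, ligands, derived labels."""

    id: str
    structure: Structure
    ligand_names: list
    nucleotide_bound: bool = field(init=False)
    rmsd_to_ref: float | None = None
    ploop_state: str | None = None

    def __post_init__(self):
        self.nucleotide_bound = classify_ligand(self.ligand_names)


def rmsd_partition(records, reference: Structure, threshold: float = 0.6,
                   atom_selection=None):
    """Partition records by backbone RMSD to ``reference``.

    "Within" means RMSD <= threshold (conformations beyond the threshold are
    the rare outliers).  Each record's ``rmsd_to_ref`` is filled in.
    Returns (within, beyond) lists.
    """
    if atom_selection is None:
        atom_selection = reference.backbone_mask()
    within, beyond = [], []
    for rec in records:
        rec.rmsd_to_ref = superpose_rmsd(rec.structure, reference, atom_selection)
        (within if rec.rmsd_to_ref <= threshold else beyond).append(rec)
    return within, beyond


@dataclass
class ContingencyTable:
    """2x2 integer counts with row/column labels."""

    counts: np.ndarray
    row_labels: tuple = ("row0", "row1")
    col_labels: tuple = ("col0", "col1")

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("contingency table is empty")


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(A = a) for a 2x2 table with fixed margins (row sums r1, r2 and
    first column sum c1), by direct log-factorial arithmetic."""
    n = r1 + r2
    b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
    if min(a, b, c, d) < 0:
        return -np.inf
    lf = lambda k: gammaln(k + 1)
    return (lf(r1) + lf(r2) + lf(c1) + lf(n - c1)
            - lf(n) - lf(a) - lf(b) - lf(c) - lf(d))


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p).  The sample odds ratio is (a*d)/(b*c) — inf if
    b*c == 0 with a*d > 0, NaN for 0/0.  The two-sided p sums the
    hypergeometric probabilities, over all tables with the same margins, of
    every table whose probability does not exceed the observed table's
    (probability-mass rule); terms are computed in log space.
    """
    if isinstance(table, ContingencyTable):
        counts = table.counts
    else:
        counts = np.asarray(table, dtype=np.int64)
        if counts.shape != (2, 2) or np.any(counts < 0):
            raise ValueError("table must be a 2x2 array of non-negative counts")
    a, b = int(counts[0, 0]), int(counts[0, 1])
    c, d = int(counts[1, 0]), int(counts[1, 1])
    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf
    else:
        odds = (a * d) / (b * c)
    r1, r2, c1 = a + b, c + d, a + c
    log_p_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    a_min, a_max = max(0, c1 - r2), min(r1, c1)
    log_terms = np.array([_log_hypergeom_pmf(k, r1, r2, c1)
                          for k in range(a_min, a_max + 1)])
    # relative tolerance guards equal-probability tables against log roundoff
    keep = log_terms <= log_p_obs + 1e-9
    p = float(np.exp(log_terms[keep]).sum())
    return odds, min(p, 1.0)


@dataclass
class EnrichmentReport:
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    cell_fractions: np.ndarray          # per-row fraction in the first column
    fraction_ci: np.ndarray             # (2, 2) rows x (lo, hi), 95% bootstrap
    n_bootstrap: int
    excluded: list


def crystal_contingency(records) -> ContingencyTable:
    """Cross-tabulate RMSD partition vs nucleotide occupancy.

    Rows are (beyond, within) the RMSD threshold — the outlier group first,
    so the sample odds ratio directly measures the depletion of
    nucleotide-bound structures among outlying conformations; columns are
    (bound, unbound).  Records must have ``rmsd_to_ref`` filled in (see
    :func:`rmsd_partition`); the partition rule is rmsd <= 0.6 Å for
    "within".
    """
    missing = [r.id for r in records if r.rmsd_to_ref is None]
    if missing:
        raise ValueError(f"records lack rmsd_to_ref: {missing[:3]}...")
    counts = np.zeros((2, 2), dtype=np.int64)
    for r in records:
        row = 0 if r.rmsd_to_ref > 0.6 else 1
        col = 0 if r.nucleotide_bound else 1
        counts[row, col] += 1
    return ContingencyTable(counts, row_labels=("beyond", "within"),
                            col_labels=("bound", "unbound"))


def enrichment_report(records, partition_rule, label_rule,
                      row_labels=("group0", "group1"),
                      col_labels=("positive", "negative"),
                      n_bootstrap: int = 1000, seed: int = 0) -> EnrichmentReport:
    """Build a 2x2 enrichment table from two boolean record rules and attach
    Fisher statistics plus bootstrap 95% intervals of the per-row positive
    fractions (resampling records with replacement).

    Records either rule cannot classify (raises or returns None) are listed
    in ``excluded`` with a warning and left out of the table.
    """
    rows, excluded = [], []
    for rec in records:
        try:
            part = partition_rule(rec)
            lab = label_rule(rec)
        except Exception:
            part = lab = None
        if part is None or lab is None:
            excluded.append(rec.id)
            continue
        rows.append((bool(part), bool(lab)))
    if excluded:
        warnings.warn(f"{len(excluded)} unclassifiable records excluded: "
                      f"{excluded[:5]}")
    if not rows:
        raise ValueError("no classifiable records")
    flags = np.array(rows)

    def _table(f):
        t = np.zeros((2, 2), dtype=np.int64)
        for part, lab in f:
            t[0 if part else 1, 0 if lab else 1] += 1
        return t

    counts = _table(flags)
    table = ContingencyTable(counts, row_labels, col_labels)
    odds, p = fisher_exact(table)
    with np.errstate(invalid="ignore"):
        fractions = counts[:, 0] / counts.sum(axis=1)

    rng = np.random.default_rng(seed)
    boots = np.full((n_bootstrap, 2), np.nan)
    for bi in range(n_bootstrap):
        resampled = flags[rng.integers(0, len(flags), len(flags))]
        t = _table(resampled)
        with np.errstate(invalid="ignore"):
            boots[bi] = t[:, 0] / t.sum(axis=1)
    ci = np.nanpercentile(boots, [2.5, 97.5], axis=0).T
    return EnrichmentReport(table=table, odds_ratio=odds, p_value=p,
                            cell_fractions=fractions, fraction_ci=ci,
                            n_bootstrap=n_bootstrap, excluded=excluded)
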