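"""Proteome mining: composition, cognate and critical bias, and statistics.

For one organism and one amino acid:

* ``n`` — cognate count of the final biosynthetic enzyme (the last
  catalytic step of the pathway, the one enzyme that can be identified
  unambiguously per pathway); when several alternative pathways are
  annotated, the minimum count is used — the most resilient route.
* ``m`` — mean cognate count per protein over the whole proteome
  (unweighted by length).
* cognate bias ``n - m`` — negative when the pathway is depleted in its
  own product, the genomic trait that defuses the starvation catch-22.
* critical bias ``n - 2m`` — the model-derived fate statistic; values at
  or below zero guarantee recovery after sudden starvation.
* composition bias — mean over proteins of (count - 0.05 * length), the
  deviation from the uniform 5%-of-length expectation.

Bias populations across organisms are tested with the exact one-sided
sign test, and profiles are clustered by single-linkage agglomeration on
Euclidean distances (rows = organisms, columns = amino acids).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import binomtest

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "AMBIGUITY_CODES",
    "Proteome",
    "EnzymeAnnotation",
    "SignTestResult",
    "ClusterResult",
    "count_cognate",
    "compute_m",
    "compute_n",
    "composition_bias",
    "bias_table",
    "sign_test",
    "sign_test_summary",
    "bias_matrix",
    "cluster_profiles",
]

#: canonical column order: the 20 standard one-letter codes
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: tolerated ambiguity / nonstandard codes; never match any standard code
AMBIGUITY_CODES = frozenset("BZXUOJ")

_VALID_RESIDUES = frozenset(AMINO_ACIDS) | AMBIGUITY_CODES


@dataclass(frozen=True)
class Proteome:
    """All protein sequences of one organism.

    ``proteins`` is a tuple of ``(protein_id, sequence)`` pairs; sequences
    are uppercase, nonempty, and drawn from the 20 standard letters plus
    tolerated ambiguity codes.
    """

    organism_id: str
    proteins: tuple

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"proteome {self.organism_id!r} has no proteins")
        cleaned = []
        for pid, seq in self.proteins:
            seq = str(seq).upper()
            if not seq:
                raise ValueError(f"protein {pid!r} in {self.organism_id!r} has an empty sequence")
            bad = set(seq) - _VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"protein {pid!r} in {self.organism_id!r} contains invalid residues {sorted(bad)}")
            cleaned.append((str(pid), seq))
        object.__setattr__(self, "proteins", tuple(cleaned))

    def sequence(self, protein_id: str) -> str | None:
        for pid, seq in self.proteins:
            if pid == protein_id:
                return seq
        return None


@dataclass(frozen=True)
class EnzymeAnnotation:
    """One (organism, protein, amino acid, pathway) final-enzyme record."""

    organism_id: str
    protein_id: str
    amino_acid: str
    pathway_id: str

    def __post_init__(self) -> None:
        if self.amino_acid not in AMINO_ACIDS:
            raise ValueError(f"amino_acid must be a standard one-letter code, got {self.amino_acid!r}")


def count_cognate(sequence: str, amino_acid: str) -> int:
    """Exact count of one standard residue in a sequence (case-insensitive).

    Ambiguity codes in the sequence never match any standard code.
    """
    if amino_acid not in AMINO_ACIDS:
        raise ValueError(f"not a standard amino-acid code: {amino_acid!r}")
    if not sequence:
        raise ValueError("empty sequence")
    return sequence.upper().count(amino_acid)


def compute_m(proteome: Proteome, amino_acid: str) -> float:
    """Mean cognate count per protein over the proteome (unweighted)."""
    counts = [count_cognate(seq, amino_acid) for _, seq in proteome.proteins]
    return float(np.mean(counts))


def compute_n(proteome: Proteome, annotations, amino_acid: str) -> int | None:
    """Cognate count of the final enzyme; minimum over alternative pathways.

    Returns ``None`` (missing) when no annotation for this amino acid and
    organism matches a protein in the proteome.  Annotations referencing
    absent proteins are skipped with a logged warning.
    """
    counts = []
    for ann in annotations:
        if ann.organism_id != proteome.organism_id or ann.amino_acid != amino_acid:
            continue
        seq = proteome.sequence(ann.protein_id)
        if seq is None:
            logger.warning(
                "annotation for %s/%s references unknown protein %r; skipped",
                ann.organism_id, ann.amino_acid, ann.protein_id)
            continue
        counts.append(count_cognate(seq, amino_acid))
    if not counts:
        return None
    return int(min(counts))


def composition_bias(proteome: Proteome, amino_acid: str) -> float:
    """Mean over proteins of (cognate count - 0.05 * protein length)."""
    devs = [count_cognate(seq, amino_acid) - 0.05 * len(seq)
            for _, seq in proteome.proteins]
    return float(np.mean(devs))


def bias_table(proteomes, annotations) -> pd.DataFrame:
    """Per (organism, amino acid) bias records as a tidy DataFrame.

    Columns: ``organism_id, aa, n, m, cognate_bias, critical_bias,
    composition_bias, n_missing``.  ``n`` and the two cognate measures are
    NaN where no final enzyme is annotated (``n_missing`` is then True).
    """
    rows = []
    for prot in proteomes:
        for aa in AMINO_ACIDS:
            m = compute_m(prot, aa)
            n = compute_n(prot, annotations, aa)
            missing = n is None
            rows.append({
                "organism_id": prot.organism_id,
                "aa": aa,
                "n": np.nan if missing else float(n),
                "m": m,
                "cognate_bias": np.nan if missing else n - m,
                "critical_bias": np.nan if missing else n - 2.0 * m,
                "composition_bias": composition_bias(prot, aa),
                "n_missing": missing,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SignTestResult:
    """Outcome of one exact one-sided sign test."""

    amino_acid: str
    n_organisms: int
    median_bias: float
    n_positive: int
    n_negative: int
    n_ties_dropped: int
    p_value: float
    direction: str  # 'low' | 'high'


def sign_test(values, direction: str = "auto", amino_acid: str = "") -> SignTestResult:
    """Exact one-sided sign test of a zero population median.

    Exact zeros are dropped (classical sign test); the remaining sign
    counts follow a Binomial(N, 1/2) under the null.  ``direction='low'``
    tests for a negative median (p = upper binomial tail of the negative
    count); ``'high'`` the mirror image; ``'auto'`` tests in the direction
    of the sample median — exploratory use only, a confirmatory p-value
    needs a declared direction.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("sign test requires at least one value")
    n_total = int(values.size)
    n_pos = int(np.sum(values > 0))
    n_neg = int(np.sum(values < 0))
    n_ties = n_total - n_pos - n_neg
    if n_pos + n_neg == 0:
        raise ValueError("all values are exact ties; the sign test is undefined")
    median = float(np.median(values))
    if direction == "auto":
        direction = "low" if median < 0 else "high"
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low', 'high' or 'auto'")
    k = n_neg if direction == "low" else n_pos
    p = binomtest(k, n_pos + n_neg, 0.5, alternative="greater").pvalue
    return SignTestResult(
        amino_acid=amino_acid, n_organisms=n_total, median_bias=median,
        n_positive=n_pos, n_negative=n_neg, n_ties_dropped=n_ties,
        p_value=float(p), direction=direction,
    )


def sign_test_summary(table: pd.DataFrame, measure: str = "cognate_bias",
                      direction: str = "auto", alpha: float = 0.001) -> pd.DataFrame:
    """Sign test per amino acid over a bias table.

    Mirrors the layout of a per-amino-acid bias summary: columns
    ``amino_acid, n_organisms, median_bias, p_value, direction,
    significant`` (raw p-values, flagged at ``p < alpha``; no
    multiple-testing correction).  Amino acids with no usable values are
    reported with ``n_organisms = 0`` and NaN statistics.
    """
    rows = []
    for aa in AMINO_ACIDS:
        vals = table.loc[(table["aa"] == aa) & table[measure].notna(), measure]
        if len(vals) == 0 or (vals == 0).all():
            rows.append({"amino_acid": aa, "n_organisms": int(len(vals)),
                         "median_bias": np.nan, "p_value": np.nan,
                         "direction": "", "significant": False})
            continue
        res = sign_test(vals, direction=direction, amino_acid=aa)
        rows.append({"amino_acid": aa, "n_organisms": res.n_organisms,
                     "median_bias": res.median_bias, "p_value": res.p_value,
                     "direction": res.direction,
                     "significant": bool(res.p_value < alpha)})
    return pd.DataFrame(rows)


def bias_matrix(table: pd.DataFrame, measure: str = "cognate_bias") -> pd.DataFrame:
    """Organisms x 20 matrix of one bias measure.

    Missing entries (pathway not found) are carried as NaN; columns follow
    the canonical amino-acid order, rows the order of first appearance.
    """
    if table.empty:
        raise ValueError("empty bias table")
    mat = table.pivot(index="organism_id", columns="aa", values=measure)
    mat = mat.reindex(columns=list(AMINO_ACIDS))
    order = table["organism_id"].drop_duplicates().tolist()
    return mat.reindex(index=order)


@dataclass
class ClusterResult:
    """Single-linkage clustering of a bias matrix, rows and columns."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list        # organism ids, dendrogram leaf order
    col_order: list        # amino acids, dendrogram leaf order
    imputed: pd.DataFrame  # matrix used for distances (column-mean imputed)


def cluster_profiles(matrix: pd.DataFrame) -> ClusterResult:
    """Agglomerative clustering of bias profiles (nearest Euclidean).

    Rows (organisms) and, independently, columns (amino acids) are
    clustered by single linkage on Euclidean distances.  Missing cells are
    imputed with their column mean before distance computation (a neutral
    choice for ordering); missingness is preserved in the input matrix for
    display.  Requires at least two rows.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering requires at least 2 rows")
    imputed = matrix.copy()
    col_means = imputed.mean(axis=0, skipna=True)
    imputed = imputed.fillna(col_means).fillna(0.0)
    X = imputed.to_numpy(dtype=float)
    row_Z = linkage(X, method="single", metric="euclidean")
    col_Z = linkage(X.T, method="single", metric="euclidean")
    row_order = [imputed.index[i] for i in leaves_list(row_Z)]
    col_order = [imputed.columns[i] for i in leaves_list(col_Z)]
    return ClusterResult(row_linkage=row_Z, col_linkage=col_Z,
                         row_order=row_order, col_order=col_order, imputed=imputed)
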