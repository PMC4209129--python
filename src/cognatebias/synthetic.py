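"""Synthetic proteome cohorts with controlled, recoverable cognate bias.

The generator emulates, at toy scale, the inputs of the proteome-mining
pipeline: per-organism amino-acid composition vectors (Dirichlet jitter
around a base composition, default uniform 0.05), log-normal protein
lengths with mean ~300 residues, and one designated final biosynthetic
enzyme per amino acid whose expected cognate count is shifted by an
injectable delta — the recoverable ground truth.  Organisms can be split
into environment groups with distinct delta profiles, and annotations can
be dropped at random to exercise the missing-pathway path downstream.

Sequences are i.i.d. multinomial per residue: the bias statistics operate
on composition counts only, so no codon structure or phylogenetic
correlation is modeled (group structure is the only non-independence).
Everything is deterministic given (seed, organism index).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_bias import AMINO_ACIDS, EnzymeAnnotation, Proteome

__all__ = [
    "SyntheticCohortConfig",
    "make_proteome",
    "make_cohort_records",
    "make_cohort",
    "make_pathway_dropout",
]

_AA_ARR = np.array(list(AMINO_ACIDS))


def _uniform_composition() -> tuple:
    return tuple([1.0 / 20.0] * 20)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions of one synthetic cohort.

    Parameters
    ----------
    seed : int
        RNG seed; mandatory, every draw derives from it.
    n_organisms, proteins_per_organism : int
        Cohort and proteome sizes.  200 proteins per organism is the
        toy-scale stand-in for a real microbial proteome.
    mean_length, length_sigma : float
        Log-normal protein-length distribution: mean ``mean_length``
        residues (default 300, the average bacterial protein) and
        log-scale dispersion ``length_sigma``.
    base_composition : tuple of 20 floats
        Residue probabilities in canonical amino-acid order; default
        uniform 0.05.  Must sum to 1.
    composition_jitter : float
        Dirichlet concentration multiplier governing per-organism
        deviation from the base composition (larger = tighter).
    group_deltas : tuple of dict
        One per environment group: per-amino-acid shifts (residues) of the
        final enzyme's expected cognate count.  Organisms are assigned to
        groups round-robin by index.  A single empty dict means one
        unbiased group.
    min_length : int
        Floor applied to sampled lengths.
    """

    seed: int
    n_organisms: int = 50
    proteins_per_organism: int = 200
    mean_length: float = 300.0
    length_sigma: float = 0.35
    base_composition: tuple = field(default_factory=_uniform_composition)
    composition_jitter: float = 2000.0
    group_deltas: tuple = ({},)
    min_length: int = 30

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_organisms < 1 or self.proteins_per_organism < 1:
            raise ValueError("counts must be positive")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (20,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must be 20 nonnegative probabilities summing to 1")
        if self.mean_length <= 0 or self.length_sigma < 0 or self.composition_jitter <= 0:
            raise ValueError("length and jitter parameters must be positive")
        if not self.group_deltas:
            raise ValueError("group_deltas must contain at least one profile")
        for prof in self.group_deltas:
            bad = set(prof) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"unknown amino acids in delta profile: {sorted(bad)}")

    @property
    def n_groups(self) -> int:
        return len(self.group_deltas)

    def group_of(self, organism_index: int) -> int:
        return organism_index % self.n_groups


def _rng_for(config: SyntheticCohortConfig, organism_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, organism_index])


def _sample_lengths(rng, config, size: int) -> np.ndarray:
    mu = np.log(config.mean_length) - 0.5 * config.length_sigma ** 2
    L = rng.lognormal(mean=mu, sigma=config.length_sigma, size=size)
    return np.maximum(np.rint(L).astype(int), config.min_length)


def _sample_sequences(rng, lengths: np.ndarray, comp: np.ndarray) -> list:
    total = int(lengths.sum())
    draws = rng.choice(20, size=total, p=comp)
    letters = _AA_ARR[draws]
    seqs, start = [], 0
    for L in lengths:
        seqs.append("".join(letters[start:start + L]))
        start += L
    return seqs


def make_proteome(config: SyntheticCohortConfig, organism_index: int):
    """One synthetic proteome plus its final-enzyme annotations and truth.

    The organism's residue composition is a Dirichlet draw around the base
    composition; bulk proteins are sampled i.i.d. at that composition.
    For each amino acid one extra protein is designated the final
    biosynthetic enzyme and sampled at a shifted composition so that its
    *expected* cognate count equals ``base_p * mean_length + delta``
    regardless of the enzyme's own sampled length (probability mass is
    taken proportionally from the other residues).  Deltas below the
    feasible floor are clamped at an expected count of zero.

    Returns ``(proteome, annotations, truth)`` where ``truth`` maps amino
    acid to the injected delta.  Deterministic given (seed, index).
    """
    rng = _rng_for(config, organism_index)
    base = np.asarray(config.base_composition, dtype=float)
    comp = rng.dirichlet(config.composition_jitter * base)
    organism_id = f"SYN{organism_index:04d}"

    lengths = _sample_lengths(rng, config, config.proteins_per_organism)
    seqs = _sample_sequences(rng, lengths, comp)
    proteins = [(f"{organism_id}_P{j:05d}", s) for j, s in enumerate(seqs)]

    deltas = config.group_deltas[config.group_of(organism_index)]
    annotations, truth = [], {}
    enz_lengths = _sample_lengths(rng, config, 20)
    for ai, aa in enumerate(AMINO_ACIDS):
        delta = float(deltas.get(aa, 0.0))
        L = int(enz_lengths[ai])
        target = comp[ai] * config.mean_length + delta
        if target < 0.0:
            import warnings
            warnings.warn(
                f"delta {delta} for {aa} drives expected count below 0; clamped",
                stacklevel=2)
            target = 0.0
        q_a = min(target / L, 0.95)
        q = comp * (1.0 - q_a) / (1.0 - comp[ai])
        q[ai] = q_a
        q = q / q.sum()
        seq = _sample_sequences(rng, np.array([L]), q)[0]
        pid = f"{organism_id}_ENZ_{aa}"
        proteins.append((pid, seq))
        annotations.append(EnzymeAnnotation(
            organism_id=organism_id, protein_id=pid,
            amino_acid=aa, pathway_id=f"{aa}-biosynthesis"))
        truth[aa] = delta

    return Proteome(organism_id=organism_id, proteins=tuple(proteins)), annotations, truth


def make_cohort_records(config: SyntheticCohortConfig):
    """Whole cohort in memory: (proteomes, annotations, truth_rows).

    ``truth_rows`` is a list of dicts with organism_id, group, amino acid
    and injected delta, for recovery tests.
    """
    proteomes, annotations, truth_rows = [], [], []
    for i in range(config.n_organisms):
        prot, anns, truth = make_proteome(config, i)
        proteomes.append(prot)
        annotations.extend(anns)
        for aa, delta in truth.items():
            truth_rows.append({"organism_id": prot.organism_id,
                               "group": config.group_of(i),
                               "aa": aa, "delta": delta})
    return proteomes, annotations, truth_rows


def make_cohort(config: SyntheticCohortConfig, out_dir) -> dict:
    """Write a cohort to disk in the dialects the pipeline consumes.

    Emits one FASTA per organism, ``manifest.tsv`` (organism_id, path),
    ``annotations.tsv`` and ``truth.csv``; returns the paths.  The
    round trip generate -> bias -> sign test runs with no manual edits.
    """
    import pandas as pd

    from .io import write_annotations_tsv, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteomes, annotations, truth_rows = make_cohort_records(config)
    manifest_rows = []
    for prot in proteomes:
        fasta = out / f"{prot.organism_id}.fasta"
        write_fasta(fasta, prot.proteins)
        manifest_rows.append({"organism_id": prot.organism_id, "fasta_path": fasta.name})
    manifest = out / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", index=False)
    ann_path = out / "annotations.tsv"
    write_annotations_tsv(ann_path, annotations)
    truth_path = out / "truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    return {"manifest": manifest, "annotations": ann_path, "truth": truth_path,
            "dir": out}


def make_pathway_dropout(config: SyntheticCohortConfig, dropout_rate: float):
    """Cohort with annotations removed at random per (organism, amino acid).

    Emulates pathways absent from a proteome: each final-enzyme annotation
    is dropped independently with probability ``dropout_rate``, so the
    downstream bias records carry missing flags and the clustering
    imputation path is exercised.  Returns the same triple as
    :func:`make_cohort_records`.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must lie in [0, 1)")
    proteomes, annotations, truth_rows = make_cohort_records(config)
    rng = np.random.default_rng([config.seed, 0x5EED])
    keep = rng.random(len(annotations)) >= dropout_rate
    annotations = [a for a, k in zip(annotations, keep) if k]
    return proteomes, annotations, truth_rows
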