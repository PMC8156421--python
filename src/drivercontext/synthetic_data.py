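"""Synthetic genomes, mutations and descriptive features for testing.

Real training data for this problem comes from curated somatic-mutation
compilations mapped onto the human reference genome plus external feature
databases, none of which are redistributable here.  This module generates
self-contained stand-ins that emulate the two properties the method relies
on:

* *class-dependent sequence context*: driver and passenger flanks are drawn
  from separate first-order Markov models over {A, C, G, T}, so k-mer
  composition differs between the classes by a controllable amount
  (identical models give exchangeable classes — the null);
* *class-shifted descriptive features*: a binary post-translational-
  modification-like flag with class rates 0.31 (drivers) vs 0.004
  (passengers), a second binary region-of-interest-like flag (0.37 vs
  0.11), and Gaussian conservation-like scores with a configurable class
  mean shift, plus an injectable missing-value mask (default rate 0.001).

Mutation windows are rewritten into the genome (spacing >= 21 bp keeps
windows disjoint at the maximum window size), so neighborhood extraction
from the written FASTA reproduces the class context exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mutation_io import BASES, MAX_WINDOW, MutationRecord

logger = logging.getLogger("drivercontext")

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def markov_uniform() -> np.ndarray:
    return np.full((4, 4), 0.25)


def markov_gc_rich(strength: float = 0.6) -> np.ndarray:
    """Transitions favoring G/C with total probability ``strength``."""
    if not 0 < strength < 1:
        raise ValueError("strength must be in (0, 1)")
    row = np.empty(4)
    for b, base in enumerate(BASES):
        row[b] = strength / 2 if base in "GC" else (1 - strength) / 2
    return np.tile(row, (4, 1))


def markov_at_rich(strength: float = 0.6) -> np.ndarray:
    if not 0 < strength < 1:
        raise ValueError("strength must be in (0, 1)")
    row = np.empty(4)
    for b, base in enumerate(BASES):
        row[b] = strength / 2 if base in "AT" else (1 - strength) / 2
    return np.tile(row, (4, 1))


@dataclass(frozen=True)
class GaussianFeatureSpec:
    """One conservation-score-like column with a class mean shift."""

    name: str
    driver_mean: float
    passenger_mean: float
    sd: float = 1.0


@dataclass(frozen=True)
class BernoulliFeatureSpec:
    """One binary annotation-like column with class-specific rates."""

    name: str
    driver_rate: float
    passenger_rate: float

    def __post_init__(self) -> None:
        for r in (self.driver_rate, self.passenger_rate):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")


#: Default descriptive features; the binary rates follow the class contrasts
#: reported for PTM-site and region-of-interest annotations in curated
#: driver/passenger data, the Gaussian columns emulate conservation scores.
DEFAULT_DESCRIPTIVE = (
    BernoulliFeatureSpec("ptm_site", 0.31, 0.004),
    BernoulliFeatureSpec("region_of_interest", 0.37, 0.11),
    GaussianFeatureSpec("conservation_a", 1.0, 0.0),
    GaussianFeatureSpec("conservation_b", 0.5, 0.0),
)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic benchmark."""

    n_contigs: int = 2
    contig_length: int = 100_000
    n_drivers: int = 500
    n_passengers: int = 1500
    driver_context: np.ndarray = field(default_factory=lambda: markov_gc_rich(0.7))
    passenger_context: np.ndarray = field(default_factory=lambda: markov_at_rich(0.7))
    gc_background: float = 0.5
    descriptive_features: tuple = DEFAULT_DESCRIPTIVE
    missing_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("driver_context", "passenger_context"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (4, 4) or np.any(mat < 0):
                raise ValueError(f"{name} must be a non-negative 4x4 matrix")
            if not np.allclose(mat.sum(axis=1), 1.0):
                raise ValueError(f"{name} rows must sum to 1")
            setattr(self, name, mat)
        if self.n_drivers < 0 or self.n_passengers < 0:
            raise ValueError("mutation counts must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.contig_length < 2 * MAX_WINDOW + 1:
            raise ValueError(
                f"contig_length must be >= {2 * MAX_WINDOW + 1}")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def _markov_sequence(rng: np.random.Generator, length: int, trans: np.ndarray) -> np.ndarray:
    # stationary start from the left-eigenvector of the transition matrix
    vals, vecs = np.linalg.eig(trans.T)
    stat = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
    stat = np.abs(stat) / np.abs(stat).sum()
    seq = np.empty(length, dtype=int)
    seq[0] = rng.choice(4, p=stat)
    for i in range(1, length):
        seq[i] = rng.choice(4, p=trans[seq[i - 1]])
    return seq


def _write_fasta(contigs: dict[str, np.ndarray], path: Path) -> None:
    base_arr = np.array(list(BASES))
    with open(path, "w") as fh:
        for name, codes in contigs.items():
            fh.write(f">{name}\n")
            seq = "".join(base_arr[codes])
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def generate_genome(spec: SyntheticSpec, path: str | Path,
                    seed: int | None = None) -> dict[str, np.ndarray]:
    """Write a uniform-background FASTA; returns the in-memory contig map."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    contigs = {
        f"ctg{i + 1}": _random_sequence(rng, spec.contig_length, spec.gc_background)
        for i in range(spec.n_contigs)
    }
    _write_fasta(contigs, Path(path))
    return contigs


def plant_mutations(
    contigs: dict[str, np.ndarray],
    spec: SyntheticSpec,
    path: str | Path,
    seed: int | None = None,
) -> list[MutationRecord]:
    """Plant labeled mutations whose +/-10 windows follow class context models.

    Each mutation site receives a fresh 21-base window sampled from its
    class's Markov model, written into the contig; the ref base is the
    (rewritten) center base and the alt base is drawn uniformly from the
    other three.  Sites are spaced >= 21 bp so windows never overlap.  The
    rewritten genome is saved to ``path``.
    """
    if spec.n_drivers == 0 or spec.n_passengers == 0:
        raise ValueError("both classes must have at least one mutation")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    span = 2 * MAX_WINDOW + 1
    slots = []
    for name, codes in contigs.items():
        n_slots = (len(codes) - 2 * MAX_WINDOW) // span
        for s in range(n_slots):
            slots.append((name, MAX_WINDOW + s * span))   # 0-based center
    total = spec.n_drivers + spec.n_passengers
    if total > len(slots):
        raise ValueError(
            f"insufficient room: {total} mutations but only {len(slots)} "
            f"non-overlapping window slots")
    chosen = rng.choice(len(slots), size=total, replace=False)
    labels = np.array(["driver"] * spec.n_drivers + ["passenger"] * spec.n_passengers)
    rng.shuffle(labels)
    records = []
    gene_pool = [f"GENE{i}" for i in range(25)]
    for slot_i, label in zip(chosen, labels):
        name, center = slots[slot_i]
        model = spec.driver_context if label == "driver" else spec.passenger_context
        window = _markov_sequence(rng, span, model)
        codes = contigs[name]
        codes[center - MAX_WINDOW:center + MAX_WINDOW + 1] = window
        ref = BASES[codes[center]]
        alt = BASES[rng.choice([b for b in range(4) if b != codes[center]])]
        records.append(MutationRecord(
            chromosome=name,
            position=center + 1,           # 1-based
            ref_base=ref,
            alt_base=alt,
            label=str(label),
            gene=gene_pool[rng.integers(len(gene_pool))],
        ))
    _write_fasta(contigs, Path(path))
    return records


def generate_descriptive_features(
    mutations: list[MutationRecord],
    spec: SyntheticSpec,
    seed: int | None = None,
) -> pd.DataFrame:
    """Class-shifted descriptive feature table keyed by mutation key."""
    if any(m.label is None for m in mutations):
        raise ValueError("all mutations must be labeled")
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    is_driver = np.array([m.label == "driver" for m in mutations])
    data = {}
    for feat in spec.descriptive_features:
        if isinstance(feat, BernoulliFeatureSpec):
            rates = np.where(is_driver, feat.driver_rate, feat.passenger_rate)
            data[feat.name] = (rng.random(len(mutations)) < rates).astype(float)
        else:
            means = np.where(is_driver, feat.driver_mean, feat.passenger_mean)
            data[feat.name] = rng.normal(means, feat.sd)
    frame = pd.DataFrame(data, index=[m.key for m in mutations])
    if spec.missing_rate > 0:
        mask = rng.random(frame.shape) < spec.missing_rate
        frame = frame.mask(mask)
    return frame


def make_benchmark(
    spec: SyntheticSpec,
    outdir: str | Path,
) -> tuple[Path, list[MutationRecord], pd.DataFrame]:
    """Generate a complete fixture: FASTA + labeled mutations + features.

    Returns (genome_path, mutations, descriptive_table); the mutation TSV
    and descriptive CSV are written alongside the FASTA.
    """
    from .mutation_io import write_mutations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_path = outdir / "genome.fa"
    contigs = generate_genome(spec, genome_path)
    mutations = plant_mutations(contigs, spec, genome_path)
    descriptive = generate_descriptive_features(mutations, spec)
    write_mutations(mutations, outdir / "mutations.tsv")
    descriptive.to_csv(outdir / "descriptive.csv", index_label="key")
    return genome_path, mutations, descriptive
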