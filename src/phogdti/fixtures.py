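"""Fully synthetic DTI benchmarks with a plantable association signal.

Real DTI gold standards (the four *enzyme* / *ion channel* / *GPCR* /
*nuclear receptor* benchmarks) require licensed interaction data and genuine
PSI-BLAST profiles.  This module fabricates stand-ins at the same scales so
every pipeline stage is exercisable offline, and plants a controllable
association signal so classification is learnable:

* every drug and protein is assigned a latent binary type;
* a pair is *compatible* when both its drug and its protein are type 1, and
  the prevalence of type 1 on each side is sized so the number of compatible
  pairs slightly exceeds the number of positives to draw — at full
  separability essentially all positives are compatible and almost all
  sampled negatives are not, so the latent types carry the labels;
* ``separability`` in [0, 1] is the probability that each positive is drawn
  from the compatible pool rather than uniformly (0 = pure noise,
  1 = fully type-determined);
* protein type is written into the PSSM as a low-frequency sinusoidal
  texture superimposed on integer noise — row-aligned stripes for type 0,
  column-aligned for type 1 — which the PHOG orientation histograms resolve;
* drug type is written into the fingerprint as a dense (type 1) or sparse
  (type 0) leading bit block, the remaining bits being background noise.

The signal lives in BOTH modalities, so ablating either one measurably
degrades accuracy.  Everything is deterministic per seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import dti_pipeline, phog_features
from .fingerprints import (
    FINGERPRINT_LENGTH,
    Fingerprint,
    write_fingerprint_table,
)
from .pssm_io import PSIBLAST_ALPHABET, Pssm, write_pssm_dir

#: Benchmark scales (n_drugs, n_proteins, n_positives) mirroring the four
#: DTI gold-standard data sets.
PRESETS: dict[str, tuple[int, int, int]] = {
    "enzyme": (445, 664, 2926),
    "ion_channel": (210, 204, 1476),
    "gpcr": (223, 95, 635),
    "nuclear_receptor": (54, 26, 90),
}

# texture parameters of the planted PSSM signal
_STRIPE_AMPLITUDE = 6
_STRIPE_PERIOD = 8
_NOISE_AMPLITUDE = 3

# fingerprint signal block: leading bits, dense for type-1 drugs
_FP_BLOCK = 40
_FP_DENSE = 0.95
_FP_SPARSE = 0.05


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of one synthetic benchmark.

    ``separability`` controls how strongly positives follow the latent
    compatible types (0 = labels carry no signal, 1 = fully
    type-determined); ``protein_length_range`` is inclusive and its minimum
    must be at least 8 so the default PHOG pyramid fits.
    """

    n_drugs: int
    n_proteins: int
    n_positives: int
    protein_length_range: tuple[int, int] = (50, 200)
    fingerprint_density: float = 0.1
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_proteins < 1:
            raise ValueError("need at least one drug and one protein")
        if not 0 <= self.n_positives <= self.n_drugs * self.n_proteins:
            raise ValueError(
                f"n_positives={self.n_positives} infeasible for "
                f"{self.n_drugs} x {self.n_proteins} candidate pairs"
            )
        if self.protein_length_range[0] < 8:
            raise ValueError("minimum protein length must be >= 8")
        if self.protein_length_range[0] > self.protein_length_range[1]:
            raise ValueError("protein_length_range must be (min, max)")
        if not 0 <= self.separability <= 1:
            raise ValueError("separability must be in [0, 1]")

    @classmethod
    def preset(cls, name: str, **overrides) -> "BenchmarkSpec":
        """A spec at one of the four gold-standard scales (see PRESETS)."""
        try:
            n_drugs, n_proteins, n_positives = PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
            ) from None
        return replace(
            cls(n_drugs=n_drugs, n_proteins=n_proteins,
                n_positives=n_positives),
            **overrides,
        )


@dataclass
class Benchmark:
    """A generated benchmark bundle plus its latent ground truth."""

    spec: BenchmarkSpec
    pssms: dict[str, Pssm]
    fingerprints: dict[str, Fingerprint]
    interactions: dti_pipeline.InteractionSet
    drug_types: dict[str, int] = field(default_factory=dict)
    protein_types: dict[str, int] = field(default_factory=dict)


def _type_counts(n_drugs: int, n_proteins: int, n_positives: int
                 ) -> tuple[int, int]:
    """Numbers of type-1 drugs/proteins so compatible pairs >= positives."""
    if n_positives == 0:
        return 1, 1
    n1_d = min(n_drugs, max(1, math.ceil(
        math.sqrt(n_positives * n_drugs / n_proteins))))
    n1_p = min(n_proteins, max(1, math.ceil(n_positives / n1_d)))
    while n1_d * n1_p < n_positives:
        if n1_d < n_drugs:
            n1_d += 1
        elif n1_p < n_proteins:
            n1_p += 1
        else:  # unreachable: n_positives <= n_drugs * n_proteins
            break
    return n1_d, n1_p


def _synthesize_pssm(
    protein_id: str, length: int, ptype: int, rng: np.random.Generator
) -> Pssm:
    """Integer PSSM: uniform noise plus a type-oriented sinusoidal stripe."""
    noise = rng.integers(-_NOISE_AMPLITUDE, _NOISE_AMPLITUDE + 1,
                         size=(length, 20))
    if ptype == 1:  # column-aligned stripes: scores vary along columns
        wave = _STRIPE_AMPLITUDE * np.sin(
            2 * np.pi * np.arange(20) / _STRIPE_PERIOD)
        pattern = np.tile(np.round(wave), (length, 1))
    else:  # row-aligned stripes: scores vary along the sequence
        wave = _STRIPE_AMPLITUDE * np.sin(
            2 * np.pi * np.arange(length) / _STRIPE_PERIOD)
        pattern = np.tile(np.round(wave)[:, None], (1, 20))
    sequence = "".join(rng.choice(list(PSIBLAST_ALPHABET), size=length))
    return Pssm(protein_id=protein_id, sequence=sequence,
                scores=(noise + pattern).astype(float))


def _synthesize_fingerprint(
    drug_id: str, dtype_: int, density: float, rng: np.random.Generator
) -> Fingerprint:
    bits = (rng.random(FINGERPRINT_LENGTH) < density).astype(np.uint8)
    block_density = _FP_DENSE if dtype_ == 1 else _FP_SPARSE
    bits[:_FP_BLOCK] = rng.random(_FP_BLOCK) < block_density
    return Fingerprint(drug_id=drug_id, bits=bits)


def _draw_positives(
    drugs: list[str],
    proteins: list[str],
    drug_types: dict[str, int],
    protein_types: dict[str, int],
    n_positives: int,
    separability: float,
    rng: np.random.Generator,
) -> set[tuple[str, str]]:
    compat = [
        (d, p)
        for d in drugs if drug_types[d] == 1
        for p in proteins if protein_types[p] == 1
    ]
    rng.shuffle(compat)
    chosen: set[tuple[str, str]] = set()
    ptr = 0  # next unused entry of the shuffled compatible pool
    while len(chosen) < n_positives:
        while ptr < len(compat) and compat[ptr] in chosen:
            ptr += 1
        from_pool = rng.random() < separability and ptr < len(compat)
        if from_pool:
            chosen.add(compat[ptr])
            ptr += 1
        else:  # uniform over all remaining candidate pairs
            while True:
                pair = (drugs[rng.integers(len(drugs))],
                        proteins[rng.integers(len(proteins))])
                if pair not in chosen:
                    chosen.add(pair)
                    break
    return chosen


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Generate PSSMs, fingerprints and an interaction set per ``spec``.

    Deterministic per seed; every generated artifact round-trips through the
    corresponding parser.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(3, len(str(max(spec.n_drugs, spec.n_proteins))))
    drugs = [f"D{i:0{width}d}" for i in range(spec.n_drugs)]
    proteins = [f"P{i:0{width}d}" for i in range(spec.n_proteins)]

    n1_d, n1_p = _type_counts(spec.n_drugs, spec.n_proteins, spec.n_positives)
    drug_types = dict.fromkeys(drugs, 0)
    for i in rng.choice(spec.n_drugs, size=n1_d, replace=False):
        drug_types[drugs[i]] = 1
    protein_types = dict.fromkeys(proteins, 0)
    for i in rng.choice(spec.n_proteins, size=n1_p, replace=False):
        protein_types[proteins[i]] = 1

    lo, hi = spec.protein_length_range
    pssms = {
        p: _synthesize_pssm(p, int(rng.integers(lo, hi + 1)),
                            protein_types[p], rng)
        for p in proteins
    }
    fingerprints = {
        d: _synthesize_fingerprint(d, drug_types[d],
                                   spec.fingerprint_density, rng)
        for d in drugs
    }
    positives = _draw_positives(
        drugs, proteins, drug_types, protein_types,
        spec.n_positives, spec.separability, rng,
    )
    interactions = dti_pipeline.InteractionSet(
        drugs=drugs, proteins=proteins, positives=positives
    )
    return Benchmark(
        spec=spec, pssms=pssms, fingerprints=fingerprints,
        interactions=interactions, drug_types=drug_types,
        protein_types=protein_types,
    )


def write_benchmark(bench: Benchmark, outdir: str | Path) -> None:
    """Write a benchmark bundle to disk in the toolkit's on-disk formats.

    Layout: ``pssms/<protein_id>.pssm``, ``fingerprints.tsv``,
    ``interactions.tsv`` (positive pairs), ``benchmark.json`` (spec).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pssm_dir(bench.pssms, outdir / "pssms")
    write_fingerprint_table(bench.fingerprints, outdir / "fingerprints.tsv")
    dti_pipeline.write_interactions(
        sorted(bench.interactions.positives), outdir / "interactions.tsv"
    )
    (outdir / "benchmark.json").write_text(json.dumps({
        "n_drugs": bench.spec.n_drugs,
        "n_proteins": bench.spec.n_proteins,
        "n_positives": bench.spec.n_positives,
        "protein_length_range": list(bench.spec.protein_length_range),
        "fingerprint_density": bench.spec.fingerprint_density,
        "separability": bench.spec.separability,
        "seed": bench.spec.seed,
    }, indent=2))


def benchmark_samples(
    bench: Benchmark,
    phog_config: phog_features.PhogConfig = phog_features.PhogConfig(),
    seed: int | None = None,
) -> list[dti_pipeline.PairSample]:
    """Balanced labelled pair samples: positives plus downsampled negatives."""
    if seed is None:
        seed = bench.spec.seed
    phog_tab = phog_features.phog_table(bench.pssms, phog_config)
    positives = sorted(bench.interactions.positives)
    negatives = dti_pipeline.sample_negatives(bench.interactions, seed=seed)
    pairs = [(d, p, 1) for d, p in positives] + [
        (d, p, 0) for d, p in negatives
    ]
    return dti_pipeline.build_pair_features(
        pairs, phog_tab, bench.fingerprints
    )


def benchmark_cv(
    spec: BenchmarkSpec,
    rf_config=None,
    folds: int = 5,
) -> dti_pipeline.CvReport:
    """End-to-end run: simulate -> PHOG extraction -> balanced pairs -> CV."""
    bench = generate_benchmark(spec)
    samples = benchmark_samples(bench)
    return dti_pipeline.cross_validate(
        samples, rf_config, folds=folds, seed=spec.seed
    )
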