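"""Synthetic somatic-mutation cohorts with planted class structure.

Real tumor cohorts reduce to extremely sparse binary gene × sample
matrices: a sample typically carries mutations in a few dozen to a few
hundred of tens of thousands of genes, and the per-gene mutation
frequency is heavy-tailed (a handful of recurrently mutated genes, a long
tail of near-private ones).  The generator emulates exactly that
structure so the filtering, encoding, and classification machinery can be
exercised end to end without external downloads:

* **background** — every gene mutates independently at a per-gene
  baseline rate drawn from a discretized power law (the heavy tail);
* **drivers** — each cancer class owns a disjoint set of genes mutated
  at an elevated rate in that class's samples only (the signal a
  classifier should find);
* **blocks** — groups of genes that co-mutate via a shared latent
  indicator, independent of class (the correlation structure that gives
  greedy Jaccard grouping real clusters to discover).

What it does not emulate: mutational signatures, per-sample mutation-rate
heterogeneity beyond the block/driver mixture, and gene–gene epistasis;
conclusions drawn from it are about the algorithmic machinery, not about
biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cgf import DiscriminatorySubset
from .io_mut import BinaryMutationMatrix, CohortLabels, write_labels_tsv


@dataclass
class BlockSpec:
    """A correlated gene block: a latent indicator fires with probability
    ``block_rate`` per sample, and while it is on each member mutates
    with probability ``within_rate``."""

    genes: tuple[int, ...]  # 1-based gene indices
    block_rate: float = 0.25
    within_rate: float = 0.9


@dataclass
class SimConfig:
    n_classes: int = 12
    m_genes: int = 500
    samples_per_class: int = 40
    drivers_per_class: int = 5
    driver_rate: float = 0.8
    background_rates: np.ndarray | None = None  # length-m per-gene rates
    mean_background_rate: float = 0.005         # used when rates are drawn
    power_law_exponent: float = 2.0
    blocks: list[BlockSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.m_genes < 1 or self.samples_per_class < 1:
            raise ValueError("sizes must be positive")
        if not 0.0 <= self.driver_rate <= 1.0:
            raise ValueError("driver_rate must lie in [0, 1]")
        if self.n_classes * self.drivers_per_class > self.m_genes:
            raise ValueError("not enough genes for disjoint driver sets")
        members = [g for b in self.blocks for g in b.genes]
        if len(members) != len(set(members)):
            raise ValueError("block gene sets must be disjoint")
        if members and (min(members) < 1 or max(members) > self.m_genes):
            raise ValueError("block gene index out of range")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort: per-class planted driver index
    sets and block memberships (all 1-based)."""

    driver_sets: list[list[int]]
    blocks: list[list[int]]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def power_law_rates(
    m: int, mean_rate: float, exponent: float, rng: np.random.Generator,
    max_rate: float = 0.3,
) -> np.ndarray:
    """Heavy-tailed per-gene baseline rates with the requested mean.

    Gene weights are Pareto(exponent − 1) draws; rates are the weights
    rescaled to ``mean_rate`` and clipped at ``max_rate`` so no
    background gene becomes implausibly recurrent.
    """
    w = 1.0 + rng.pareto(exponent - 1.0, size=m)
    rates = mean_rate * w / w.mean()
    return np.clip(rates, 0.0, max_rate)


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[BinaryMutationMatrix, CohortLabels, SimTruth]:
    """Draw one cohort; fully deterministic under ``cfg.seed``.

    Gene ids are zero-padded (``G00001`` …) so lexicographic order equals
    index order; samples are grouped by class, ``n_classes ×
    samples_per_class`` columns in total.
    """
    rng = np.random.default_rng(cfg.seed)
    m, n_cls, per = cfg.m_genes, cfg.n_classes, cfg.samples_per_class
    n = n_cls * per

    block_members = sorted(g for b in cfg.blocks for g in b.genes)
    free = [g for g in range(1, m + 1) if g not in set(block_members)]
    if len(free) < n_cls * cfg.drivers_per_class:
        raise ValueError("not enough non-block genes for driver sets")
    chosen = rng.choice(len(free), size=n_cls * cfg.drivers_per_class, replace=False)
    chosen = np.sort(np.asarray(free, dtype=np.int64)[chosen])
    driver_sets = [
        sorted(chosen[c::n_cls].tolist()) for c in range(n_cls)
    ] if cfg.drivers_per_class else [[] for _ in range(n_cls)]

    bg = cfg.background_rates
    if bg is None:
        bg = power_law_rates(m, cfg.mean_background_rate, cfg.power_law_exponent, rng)
    bg = np.asarray(bg, dtype=np.float64)
    if bg.shape != (m,):
        raise ValueError(f"background_rates has shape {bg.shape}, expected ({m},)")

    # per-sample gene rates: background, overridden by block/driver states
    values = np.zeros((m, n), dtype=np.uint8)
    labels = np.repeat(np.arange(1, n_cls + 1), per)
    for j in range(n):
        rates = bg.copy()
        for b in cfg.blocks:
            idx = np.asarray(b.genes, dtype=np.int64) - 1
            if rng.random() < b.block_rate:
                rates[idx] = b.within_rate
        for g in driver_sets[labels[j] - 1]:
            rates[g - 1] = cfg.driver_rate
        values[:, j] = rng.random(m) < rates

    matrix = BinaryMutationMatrix(
        values=values,
        gene_ids=[f"G{i:05d}" for i in range(1, m + 1)],
        sample_ids=[f"S{j:04d}" for j in range(1, n + 1)],
    )
    cohort = CohortLabels(labels, [f"CLASS{c:02d}" for c in range(1, n_cls + 1)])
    truth = SimTruth(driver_sets=driver_sets,
                     blocks=[sorted(b.genes) for b in cfg.blocks])
    return matrix, cohort, truth


def driver_recovery(subset: DiscriminatorySubset, truth: SimTruth) -> float:
    """Recall of the planted drivers in a selected gene subset."""
    drivers = {g for ds in truth.driver_sets for g in ds}
    if not drivers:
        return 1.0  # vacuously: every planted driver (none) is present
    return len(drivers & set(subset.gene_indices.tolist())) / len(drivers)


def _blocks(start: int, n_blocks: int, size: int, **kw) -> list[BlockSpec]:
    return [
        BlockSpec(genes=tuple(range(start + b * size, start + (b + 1) * size)), **kw)
        for b in range(n_blocks)
    ]


def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named study configurations.

    * ``toy`` — 3 classes × 10 samples, 40 genes; fast unit-test scale.
    * ``strong`` — 12 classes × 40 samples, 500 genes, 5 drivers/class at
      rate 0.8 over a 0.005 mean background, 4 correlated blocks; a
      cohort a competent pipeline should classify almost perfectly.
    * ``null`` — 12 classes sharing one background (plus blocks, so the
      gene filter still finds structure) and no drivers: any downstream
      accuracy above chance indicates leakage.
    * ``confounded`` — the ``strong`` signal plus 150 *rare* co-mutation
      blocks (3 genes, indicator rate 0.05): striking correlated
      patterns that carry no class information.  A classifier fed the
      raw matrix memorizes them; the gene filter's group-size threshold
      discards them wholesale, which is the regime where filtering
      beats raw input.
    * ``tcga-like`` — 22,834 genes, 12 classes, heavy-tailed background
      calibrated to ~155 expected mutations per sample, so nearly all
      samples carry fewer than 800 non-zero genes.
    """
    presets = {
        "toy": dict(
            n_classes=3, m_genes=40, samples_per_class=10, drivers_per_class=3,
            driver_rate=0.9, mean_background_rate=0.05,
            blocks=_blocks(2, 1, 4, block_rate=0.3, within_rate=0.9),
        ),
        "strong": dict(
            n_classes=12, m_genes=500, samples_per_class=40, drivers_per_class=5,
            driver_rate=0.8, mean_background_rate=0.005,
            blocks=_blocks(1, 4, 6, block_rate=0.25, within_rate=0.9),
        ),
        "confounded": dict(
            n_classes=12, m_genes=1000, samples_per_class=30, drivers_per_class=5,
            driver_rate=0.8, mean_background_rate=0.005,
            blocks=_blocks(1, 4, 6, block_rate=0.25, within_rate=0.9)
            + _blocks(25, 150, 3, block_rate=0.05, within_rate=0.9),
        ),
        "null": dict(
            n_classes=12, m_genes=200, samples_per_class=20, drivers_per_class=0,
            driver_rate=0.0, mean_background_rate=0.01,
            blocks=_blocks(1, 6, 6, block_rate=0.3, within_rate=0.9),
        ),
        "tcga-like": dict(
            n_classes=12, m_genes=22834, samples_per_class=260,
            drivers_per_class=10, driver_rate=0.3,
            mean_background_rate=150.0 / 22834,
            blocks=_blocks(1, 8, 10, block_rate=0.2, within_rate=0.8),
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    cfg = {**presets[name], "seed": seed, **overrides}
    return SimConfig(**cfg)


def desk_scale_params():
    """Filtering/encoding/network settings paired with the reduced-scale
    presets above.

    The similarity threshold drops to 0.4 because with 12 balanced
    classes a class-specific driver pair mutated at rate 0.8 has an
    expected cohort-wide Jaccard of roughly 0.6 (0.64/0.96 within the
    class, diluted by background co-mutations elsewhere), while
    unrelated genes sit near 0 — 0.4 splits the two regimes with margin
    on both sides.  The index-vector length 50 and a 2 × 64 network
    scale the 800/8192-unit full-size configuration down to the preset
    gene counts; the training schedule (50 epochs, log-spaced learning
    rate 1e-1 → 1e-4, weight decay 5e-4) is unchanged apart from a
    batch size of 64 matched to the smaller cohorts.
    """
    from .dnn import NetworkConfig, TrainConfig
    from .isr import IsrParams
    from .cgf import CgfParams

    return (
        CgfParams(d_cgf=0.4, n_cgf=5),
        IsrParams(n_isr=50),
        NetworkConfig(input_dim=1, hidden_layers=2, units_per_layer=64),
        TrainConfig(max_epochs=50, batch_size=64, seed=0),
    )


def write_cohort(
    out_dir, matrix: BinaryMutationMatrix, labels: CohortLabels, truth: SimTruth
) -> None:
    """Emit the cohort in the formats the readers consume: a MAF-like TSV
    of one record per mutated (gene, sample) pair, a labels TSV, and the
    ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, samples = np.nonzero(matrix.values)
    with open(out / "mutations.maf.tsv", "w") as fh:
        fh.write("Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n")
        for g, s in zip(genes, samples):
            fh.write(f"{matrix.gene_ids[g]}\t{matrix.sample_ids[s]}\tMissense_Mutation\n")
    write_labels_tsv(labels, matrix.sample_ids, out / "labels.tsv")
    truth.to_json(out / "truth.json")
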