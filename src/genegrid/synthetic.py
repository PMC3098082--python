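"""Synthetic two-class expression data with known ground truth.

The generator draws a genes x samples matrix of baseline expression plus
Gaussian noise; a minority of "informative" genes get a class-conditional
mean shift of ``effect_size`` noise standard deviations, upward (in the
positive class) for up-regulated genes and downward for down-regulated
ones.  Optionally a fraction of samples become outliers carrying an
additive spike on a random gene subset, emulating the kind of single-array
artifact the composite (feature-vector addition) transform is meant to
absorb.  Ground truth (which genes are informative and in what direction)
is returned alongside and can be written to a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .dataio import ExpressionDataset, write_dataset

__all__ = ["SimulationConfig", "generate_dataset", "write_truth", "read_truth"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror a desk-scale two-class microarray comparison: 2000
    genes, 30 samples per class, 20 up- and 20 down-regulated informative
    genes shifted by 2 noise SDs, unit Gaussian noise around a baseline of
    8 (a typical log2-intensity level), and no outlier samples unless
    requested.
    """

    n_genes: int = 2000
    n1: int = 30
    n2: int = 30
    n_informative_up: int = 20
    n_informative_down: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    base_level: float = 8.0
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 5.0
    outlier_gene_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_informative_up + self.n_informative_down > self.n_genes:
            raise ValueError("more informative genes than genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if min(self.n1, self.n2) < 2:
            raise ValueError("each class needs at least 2 samples")


def generate_dataset(cfg: SimulationConfig) -> tuple[ExpressionDataset, dict]:
    """Simulate a dataset and its ground-truth record.

    The positive class is named ``case`` (lexicographically before
    ``control``, so it is also the default positive class after a
    round-trip through the tab-delimited dialect).
    """
    rng = np.random.default_rng(cfg.seed)
    g, n = cfg.n_genes, cfg.n1 + cfg.n2
    matrix = cfg.base_level + rng.normal(0.0, cfg.noise_sd, size=(g, n))

    informative = rng.choice(g, size=cfg.n_informative_up + cfg.n_informative_down,
                             replace=False)
    up_idx = np.sort(informative[: cfg.n_informative_up])
    down_idx = np.sort(informative[cfg.n_informative_up:])
    shift = cfg.effect_size * cfg.noise_sd
    case = np.arange(cfg.n1)  # first n1 columns are the positive class
    matrix[np.ix_(up_idx, case)] += shift
    matrix[np.ix_(down_idx, case)] -= shift

    n_out = int(round(cfg.outlier_fraction * n))
    outlier_samples = np.sort(rng.choice(n, size=n_out, replace=False)) if n_out else np.asarray([], dtype=int)
    for s in outlier_samples:
        n_spiked = max(1, int(round(cfg.outlier_gene_fraction * g)))
        spiked = rng.choice(g, size=n_spiked, replace=False)
        matrix[spiked, s] += cfg.outlier_magnitude * cfg.noise_sd

    width = len(str(g))
    gene_ids = [f"g{i:0{width}d}" for i in range(g)]
    sample_ids = [f"s{j:03d}" for j in range(n)]
    labels = ["case"] * cfg.n1 + ["control"] * cfg.n2
    ds = ExpressionDataset(matrix, gene_ids, sample_ids, labels, positive_class="case")
    truth = {
        "informative_up": [gene_ids[i] for i in up_idx],
        "informative_down": [gene_ids[i] for i in down_idx],
        "outlier_samples": [sample_ids[s] for s in outlier_samples],
        "config": asdict(cfg),
    }
    return ds, truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def simulate_to_dir(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.tsv (dataio dialect) and truth.json into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = generate_dataset(cfg)
    matrix_path = out / "matrix.tsv"
    truth_path = out / "truth.json"
    write_dataset(ds, matrix_path)
    write_truth(truth, truth_path)
    return {"matrix": matrix_path, "truth": truth_path}
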