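"""Factorial synthetic expression benchmark.

Cells are drawn from an a x b Cartesian product of two categorical
features (default 2 x 2, 250 cells per type).  Genes fall into four blocks:
means shifted by +/- effect_size according to the level of feature i, of
feature j, of their interaction (product of the two level signs), or pure
noise.  Signal-block genes carry independent Gaussian noise of SD sigma;
noise-block genes are high-dispersion nuisance genes with SD
``sqrt(baseline^2 + (multiplier * sigma)^2)``, emulating the strongly
variable but phenotype-uninformative genes of real expression data.
A sigma sweep runs the model and all baselines over replicated datasets
and tabulates the metric suite (mean +/- standard error).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .baselines import cca_embed, lda_embed, pca_embed, two_ldas_embed
from .datatypes import ExpressionMatrix, FactorDesign
from .metrics import overall_report
from .model import FLDA

__all__ = ["SyntheticSpec", "generate", "run_methods", "sigma_sweep", "default_calibration"]

METHODS = ("flda", "two_ldas", "lda", "cca", "pca")


def default_calibration() -> dict:
    """Generator constants (effect size, block fractions) from the packaged
    calibration file."""
    ref = importlib.resources.files("flda").joinpath("calibration.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass
class SyntheticSpec:
    """Benchmark generator settings.

    a, b : levels of the two features (2 x 2 default -> 4 cell types)
    cells_per_type : 250 by default
    g : total genes (1000 by default), split by ``gene_blocks``
    effect_size : +/- mean shift per informative gene (calibration default)
    sigma : within-type Gaussian noise SD
    """

    a: int = 2
    b: int = 2
    cells_per_type: int = 250
    g: int = 1000
    gene_blocks: dict[str, int] | None = None
    effect_size: float | None = None
    sigma: float = 2.0
    noise_block_sd_baseline: float | None = None
    noise_block_sigma_multiplier: float | None = None
    seed: int = 0
    _calib: dict = field(default_factory=default_calibration, repr=False)

    def __post_init__(self) -> None:
        if self.effect_size is None:
            self.effect_size = float(self._calib["effect_size"])
        if self.noise_block_sd_baseline is None:
            self.noise_block_sd_baseline = float(self._calib["noise_block_sd_baseline"])
        if self.noise_block_sigma_multiplier is None:
            self.noise_block_sigma_multiplier = float(
                self._calib["noise_block_sigma_multiplier"]
            )
        if self.gene_blocks is None:
            fr = self._calib["block_fractions"]
            blocks = {k: int(round(fr[k] * self.g)) for k in ("feature_i", "feature_j", "interaction")}
            blocks["noise"] = self.g - sum(blocks.values())
            self.gene_blocks = blocks
        if sum(self.gene_blocks.values()) != self.g:
            raise ValueError("gene block sizes must sum to g")
        if self.cells_per_type < 2:
            raise ValueError("cells_per_type must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _level_signs(n_levels: int) -> np.ndarray:
    """Balanced +/-1 pattern over levels (alternating for > 2 levels)."""
    return np.array([1.0 if k % 2 == 0 else -1.0 for k in range(n_levels)])


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, FactorDesign]:
    """Draw one benchmark dataset; byte-identical under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    a, b, m, g = spec.a, spec.b, spec.cells_per_type, spec.g
    n = a * b * m
    si, sj = _level_signs(a), _level_signs(b)

    blocks = spec.gene_blocks
    slices, start = {}, 0
    for key in ("feature_i", "feature_j", "interaction", "noise"):
        slices[key] = slice(start, start + blocks[key])
        start += blocks[key]

    # per-gene random orientation keeps blocks heterogeneous without
    # changing the rank-one signal geometry
    orient = rng.choice([-1.0, 1.0], size=g)

    labels = []
    means = np.zeros((g, a * b))
    for t, (i, j) in enumerate((i, j) for i in range(a) for j in range(b)):
        mu = np.zeros(g)
        mu[slices["feature_i"]] = spec.effect_size * si[i]
        mu[slices["feature_j"]] = spec.effect_size * sj[j]
        mu[slices["interaction"]] = spec.effect_size * si[i] * sj[j]
        means[:, t] = mu * orient
        labels.extend([(f"i{i + 1}", f"j{j + 1}")] * m)

    noise_sd = np.full(g, spec.sigma)
    noise_sd[slices["noise"]] = np.sqrt(
        spec.noise_block_sd_baseline**2
        + (spec.noise_block_sigma_multiplier * spec.sigma) ** 2
    )
    type_of_cell = np.repeat(np.arange(a * b), m)
    X = means[:, type_of_cell] + noise_sd[:, None] * rng.standard_normal((g, n))
    em = ExpressionMatrix(
        X,
        [f"g{k + 1}" for k in range(g)],
        [f"c{k + 1}" for k in range(n)],
        layer_tag="log",
    )
    fd = FactorDesign(
        cell_ids=list(em.cell_ids),
        features=["feature_i", "feature_j"],
        labels=labels,
    )
    return em, fd


def run_methods(
    em: ExpressionMatrix,
    fd: FactorDesign,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    reference: str = "lda",
):
    """Fit the model and all baselines on one dataset and evaluate them.

    The comparison uses the main-effect discriminants of the model (one per
    feature on a 2 x 2 design) against the top-two components of PCA, CCA
    and LDA, and both axes of the two-separate-LDAs scheme.  Returns a map
    method -> MetricsReport.
    """
    res = FLDA(
        em, fd, lambda1=lambda1, lambda2=lambda2,
        dims={"feature_i": 1, "feature_j": 1},
    ).fit()
    proj = res.project()
    type_labels = fd.type_labels()

    embeddings = {
        "flda": (proj.coordinates, proj.axis_tags),
    }
    tl = two_ldas_embed(em, fd)
    embeddings["two_ldas"] = (tl.coordinates, tl.axis_tags)
    ld = lda_embed(em, type_labels, r=2)
    embeddings["lda"] = (ld.coordinates, ld.axis_tags)
    cc = cca_embed(em, fd, r=2)
    embeddings["cca"] = (cc.coordinates, cc.axis_tags)
    pc = pca_embed(em, r=2)
    embeddings["pca"] = (pc.coordinates, pc.axis_tags)
    return overall_report(embeddings, fd, reference=reference)


def sigma_sweep(
    spec: SyntheticSpec | None = None,
    sigmas: tuple[float, ...] = (2, 4, 6, 8, 10),
    reps: int = 10,
) -> dict[str, pd.DataFrame]:
    """Replicated noise sweep over all methods.

    For each sigma and replicate (seed = spec.seed + rep) a fresh dataset is
    generated and every method is fitted and scored.  Returns long-format
    per-replicate values plus mean +/- standard error tables of silhouette
    ("table1"), LDA-normalized overall SNR ("fig2b") and overall modularity
    ("fig2c").  With a single replicate the standard errors are reported as
    0 and flagged in the ``se_defined`` column.
    """
    base = spec or SyntheticSpec()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    records = []
    for sigma in sigmas:
        for rep in range(reps):
            s = SyntheticSpec(
                a=base.a, b=base.b, cells_per_type=base.cells_per_type, g=base.g,
                gene_blocks=dict(base.gene_blocks), effect_size=base.effect_size,
                sigma=float(sigma), seed=base.seed + rep,
                noise_block_sd_baseline=base.noise_block_sd_baseline,
                noise_block_sigma_multiplier=base.noise_block_sigma_multiplier,
            )
            em, fd = generate(s)
            reports = run_methods(em, fd)
            for method in METHODS:
                rep_obj = reports[method]
                records.append(
                    {
                        "sigma": float(sigma),
                        "rep": rep,
                        "method": method,
                        "silhouette": rep_obj.silhouette,
                        "snr_normalized": rep_obj.overall_snr_normalized,
                        "overall_snr": rep_obj.overall_snr,
                        "modularity": rep_obj.overall_modularity,
                    }
                )
    long = pd.DataFrame.from_records(records)

    def _table(metric: str) -> pd.DataFrame:
        grouped = long.groupby(["sigma", "method"])[metric]
        mean = grouped.mean().unstack()[list(METHODS)]
        if reps > 1:
            se = (grouped.std(ddof=1) / np.sqrt(reps)).unstack()[list(METHODS)]
        else:
            se = mean * 0.0
        out = mean.copy()
        for m in METHODS:
            out[f"{m}_se"] = se[m]
        out["se_defined"] = reps > 1
        return out

    return {
        "long": long,
        "table1": _table("silhouette"),
        "fig2b": _table("snr_normalized"),
        "fig2c": _table("modularity"),
    }
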