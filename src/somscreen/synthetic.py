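"""Synthetic expression panels with known ground truth.

The generator emulates the structure of a replicated protein panel from an
eight-class mouse study: per-protein baselines spanning heterogeneous
ranges, a mouse-level random effect that correlates the replicates of a
mouse, replicate-level technical noise, planted class effects tied to the
three design factors, sporadic missing cells and an optional near-empty
outlier mouse.

The generative model for mouse m (class k), protein j, replicate r is

    e_mjr = mu_j + sum_f delta_jf * sigma_j * x_f(k) + b_mj + eps_mjr

with mu_j log-uniform over the configured scale range, sigma_j = cv * mu_j
the pooled per-measurement standard deviation of the protein,
b_mj ~ N(0, (mouse_sd * sigma_j)^2), eps ~ N(0, (replicate_sd * sigma_j)^2)
and x_f(k) in {0, 1} the factor indicator of class k.  The default
variance split puts biological (between-mouse) and technical (replicate)
components on an equal footing (intraclass correlation ~0.5) with
mouse_sd^2 + replicate_sd^2 ~= 1, so planted effect sizes delta are in
pooled-SD units and scale-free across proteins.  Values are
clipped at zero (expression levels are non-negative).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .classes import ALL_CLASSES, MouseClass
from .dataset import ExpressionDataset

#: Factor indicators over class (genotype, behavior, treatment).
_FACTORS = {
    "learning": lambda c: c.behavior == "CS",
    "drug": lambda c: c.treatment == "memantine",
    "genotype": lambda c: c.genotype == "trisomic",
}


def _factor_value(factor: str, c: MouseClass) -> int:
    """Indicator of a main factor or a ':'-joined interaction term."""
    value = 1
    for part in factor.split(":"):
        if part not in _FACTORS:
            raise ValueError(f"unknown factor {part!r}")
        value *= int(_FACTORS[part](c))
    return value


def default_effect_map(delta: float = 1.5,
                       n_learning: int = 28, n_drug: int = 12,
                       n_genotype: int = 14) -> dict[str, dict[int, float]]:
    """Planted effects at the scale typical of this kind of study: a broad
    learning response, a smaller drug response and a genotype shift, on
    disjoint protein blocks."""
    out: dict[str, dict[int, float]] = {}
    start = 0
    for name, n in (("learning", n_learning), ("drug", n_drug),
                    ("genotype", n_genotype)):
        out[name] = {j: delta for j in range(start, start + n)}
        start += n
    return out


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings.

    Defaults mirror the real design: 8 classes x 8 mice x 15 replicates,
    77 proteins with baselines log-uniform in 0.6-3.0 (so some columns span
    roughly 0-3 and others well under 1), within-mouse correlated noise and
    sporadic missing cells.
    """

    n_proteins: int = 77
    mice_per_class: int | Mapping[str, int] = 8
    replicates: int = 15
    protein_scale_range: tuple[float, float] = (0.6, 3.0)
    effect_map: Mapping[str, Mapping[int, float]] = field(default_factory=default_effect_map)
    cv: float = 0.2                 # sigma_j = cv * mu_j
    mouse_sd: float = 0.7           # in sigma_j units
    replicate_sd: float = 0.71      # in sigma_j units
    missing_rate: float = 0.005
    outlier_mouse: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.replicates < 1:
            raise ValueError("n_proteins and replicates must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.mouse_sd <= 0 or self.replicate_sd <= 0 or self.cv <= 0:
            raise ValueError("sds must be positive")
        lo, hi = self.protein_scale_range
        if not (0 < lo <= hi):
            raise ValueError("bad protein_scale_range")
        for factor, effects in self.effect_map.items():
            _factor_value(factor, ALL_CLASSES[0])  # validates factor name
            for j in effects:
                if not (0 <= j < self.n_proteins):
                    raise ValueError(f"effect protein index {j} out of range")

    def n_mice(self, mouse_class: MouseClass) -> int:
        if isinstance(self.mice_per_class, Mapping):
            return int(self.mice_per_class[mouse_class.code])
        return int(self.mice_per_class)


@dataclass
class SyntheticTruth:
    """Ground truth derived from the effect map.

    ``discriminant_sets`` gives, for each catalogued comparison, the
    protein names whose planted effects differ between the two classes.
    Truth depends only on the effect map, never on noise draws.
    """

    discriminant_sets: dict[str, set[str]]
    outlier_mouse: str | None = None


def _protein_names(n: int) -> list[str]:
    return [f"P{j + 1:03d}" for j in range(n)]


def _truth_sets(config: SyntheticConfig) -> dict[str, set[str]]:
    from .discriminant import COMPARISONS, EXTRA_COMPARISONS

    names = _protein_names(config.n_proteins)
    out: dict[str, set[str]] = {}
    for cname, cmp in {**COMPARISONS, **EXTRA_COMPARISONS}.items():
        truth: set[str] = set()
        for factor, effects in config.effect_map.items():
            xa = _factor_value(factor, cmp.class_a)
            xb = _factor_value(factor, cmp.class_b)
            if xa == xb:
                continue
            truth |= {names[j] for j, d in effects.items() if d != 0}
        out[cname] = truth
    return out


def generate(config: SyntheticConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw a dataset (and its ground truth) from the generative model."""
    rng = np.random.default_rng(config.seed)
    names = _protein_names(config.n_proteins)
    lo, hi = config.protein_scale_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_proteins))
    sigma = config.cv * mu

    shift = {c.code: np.zeros(config.n_proteins) for c in ALL_CLASSES}
    for factor, effects in config.effect_map.items():
        for c in ALL_CLASSES:
            x = _factor_value(factor, c)
            if x:
                for j, d in effects.items():
                    shift[c.code][j] += d * sigma[j]

    rows, mouse_ids, classes = [], [], []
    for c in ALL_CLASSES:
        for i in range(config.n_mice(c)):
            mouse = f"{c.code}-{i + 1:02d}"
            b = rng.normal(0.0, config.mouse_sd * sigma)
            eps = rng.normal(0.0, config.replicate_sd * sigma,
                             size=(config.replicates, config.n_proteins))
            block = mu + shift[c.code] + b + eps
            rows.append(block)
            mouse_ids.extend([mouse] * config.replicates)
            classes.extend([c] * config.replicates)
    values = np.clip(np.vstack(rows), 0.0, None)
    ds = ExpressionDataset(values, names, np.asarray(mouse_ids, dtype=object),
                           classes, normalized=False)
    truth = SyntheticTruth(_truth_sets(config))

    if config.missing_rate > 0:
        ds = inject_missing(ds, config.missing_rate,
                            seed=int(rng.integers(2 ** 31)))
    if config.outlier_mouse:
        ds, outlier = inject_outlier_mouse(ds, seed=int(rng.integers(2 ** 31)))
        truth = replace(truth, outlier_mouse=outlier)
    return ds, truth


def inject_missing(ds: ExpressionDataset, rate: float, seed: int) -> ExpressionDataset:
    """Blank each cell independently with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return ds
    rng = np.random.default_rng(seed)
    mask = rng.random(ds.values.shape) < rate
    values = ds.values.copy()
    values[mask] = np.nan
    return replace(ds, values=values)


def inject_outlier_mouse(ds: ExpressionDataset, seed: int) -> tuple[ExpressionDataset, str]:
    """Turn one randomly chosen mouse into a near-empty outlier.

    60% of its protein columns are blanked entirely and its remaining
    values are shifted upward by five pooled standard deviations, mimicking
    a sample with mostly failed spots and aberrant intensities.  No other
    mouse's rows are touched.
    """
    mice = ds.mice
    if not mice:
        raise ValueError("dataset has no mice")
    rng = np.random.default_rng(seed)
    mouse = mice[int(rng.integers(len(mice)))]
    rows = np.nonzero(ds.mouse_ids == mouse)[0]
    n_blank = int(np.ceil(0.6 * ds.n_proteins))
    blanked = rng.choice(ds.n_proteins, size=n_blank, replace=False)
    values = ds.values.copy()
    col_sd = np.nanstd(values, axis=0)
    values[np.ix_(rows, blanked)] = np.nan
    keep = np.setdiff1d(np.arange(ds.n_proteins), blanked)
    values[np.ix_(rows, keep)] += 5.0 * col_sd[keep]
    return replace(ds, values=values), str(mouse)
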