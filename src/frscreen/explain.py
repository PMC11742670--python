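"""Local surrogate explanations for single IC50 predictions.

A prediction is explained LIME-style: descriptors are discretized into
quartile bins, perturbed samples around the instance toggle each feature
between "same bin as the instance" and "a random other bin", the black-box
regressor scores the reconstructed vectors, and a distance-weighted ridge
regression on the binary same-bin indicators yields one signed weight per
feature.  Positive weights support the prediction (the instance's bin for
that feature pushes the predicted IC50 up), negative weights oppose it.
Condition labels render the instance's bin as a range, e.g.
``-0.10 < mZagreb2 <= 0.41``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score

from .chem_io import DescriptorTable

__all__ = [
    "FeatureBins",
    "Explanation",
    "discretize_features",
    "sample_perturbations",
    "fit_local_surrogate",
    "render_explanation",
    "plot_explanation",
]

DEFAULT_N_SAMPLES = 5000
DEFAULT_KEEP_PROBABILITY = 0.5
DEFAULT_RIDGE_ALPHA = 1.0


def default_kernel_width(n_features: int) -> float:
    """Conventional LIME kernel width, 0.75·sqrt(#features)."""
    return 0.75 * np.sqrt(n_features)


@dataclass(frozen=True)
class FeatureBins:
    """Quartile discretization: per-feature edges, data bounds, labels."""

    feature_names: tuple[str, ...]
    edges: dict  # name -> (q1, q2, q3); degenerate features map to None
    bounds: dict  # name -> (data min, data max)
    degenerate: frozenset[str] = frozenset()

    def n_bins(self, name: str) -> int:
        return 1 if name in self.degenerate else 4

    def bin_of(self, name: str, value: float) -> int:
        """Bin index with the <= convention: a value on an edge falls low."""
        if name in self.degenerate:
            return 0
        q1, q2, q3 = self.edges[name]
        return int(np.searchsorted([q1, q2, q3], value, side="left"))

    def interval(self, name: str, b: int) -> tuple[float, float]:
        """Concrete support of bin ``b`` for drawing perturbed values."""
        lo, hi = self.bounds[name]
        if name in self.degenerate:
            return lo, hi
        cuts = (lo, *self.edges[name], hi)
        return cuts[b], cuts[b + 1]

    def label(self, name: str, b: int) -> str:
        if name in self.degenerate:
            return f"{name} = {self.bounds[name][0]:.2f}"
        q1, q2, q3 = self.edges[name]
        if b == 0:
            return f"{name} <= {q1:.2f}"
        if b == 3:
            return f"{name} > {q3:.2f}"
        lo, hi = ((q1, q2), (q2, q3))[b - 1]
        return f"{lo:.2f} < {name} <= {hi:.2f}"


def discretize_features(table: DescriptorTable) -> FeatureBins:
    """Quartile bin edges per feature; constant features get one flagged bin."""
    if table.n_compounds < 4:
        raise ValueError("discretize_features requires at least 4 rows")
    edges, bounds, degenerate = {}, {}, set()
    for j, name in enumerate(table.feature_names):
        col = table.values[:, j]
        bounds[name] = (float(col.min()), float(col.max()))
        if col.min() == col.max():
            edges[name] = None
            degenerate.add(name)
            continue
        q1, q2, q3 = np.quantile(col, [0.25, 0.5, 0.75])
        edges[name] = (float(q1), float(q2), float(q3))
    return FeatureBins(tuple(table.feature_names), edges, bounds, frozenset(degenerate))


@dataclass
class Explanation:
    """Signed per-feature weights for one prediction, sorted by |weight|."""

    instance_id: str
    entries: list[tuple[str, str, float]]  # (condition_label, feature, weight)
    intercept: float
    r2: float
    n_samples: int
    seed: int
    kernel_width: float

    def __post_init__(self) -> None:
        feats = [f for _, f, _ in self.entries]
        if len(set(feats)) != len(feats):
            raise ValueError("each feature may appear at most once")
        self.entries = sorted(self.entries, key=lambda e: (-abs(e[2]), e[1]))

    def weight(self, feature: str) -> float:
        for _, f, w in self.entries:
            if f == feature:
                return w
        raise KeyError(feature)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "instance_id": self.instance_id,
                "entries": [list(e) for e in self.entries],
                "intercept": self.intercept,
                "r2": self.r2,
                "n_samples": self.n_samples,
                "seed": self.seed,
                "kernel_width": self.kernel_width,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, text: str) -> "Explanation":
        d = json.loads(text)
        return cls(
            d["instance_id"],
            [(e[0], e[1], e[2]) for e in d["entries"]],
            d["intercept"],
            d["r2"],
            d["n_samples"],
            d["seed"],
            d["kernel_width"],
        )


def sample_perturbations(
    instance: np.ndarray,
    bins: FeatureBins,
    n: int,
    seed: int,
    keep_probability: float = DEFAULT_KEEP_PROBABILITY,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` perturbed neighbours of ``instance``.

    Returns ``(Z, X)``: Z is the binary interpretable matrix (1 = feature
    kept in the instance's bin, 0 = moved to a random other bin), X the
    reconstructed concrete descriptor vectors with values drawn uniformly
    inside the chosen bin.  Row 0 is the unperturbed instance (all ones).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    instance = np.asarray(instance, dtype=float)
    f = len(bins.feature_names)
    if instance.shape != (f,):
        raise ValueError(f"instance must have {f} values")
    rng = np.random.default_rng(seed)
    z = np.ones((n, f), dtype=int)
    x = np.tile(instance, (n, 1))
    inst_bins = [bins.bin_of(name, instance[j]) for j, name in enumerate(bins.feature_names)]
    for j, name in enumerate(bins.feature_names):
        if name in bins.degenerate:
            continue  # nothing to toggle: keep as-is, z stays 1
        keep = rng.random(n - 1) < keep_probability
        z[1:, j] = keep.astype(int)
        others = [b for b in range(bins.n_bins(name)) if b != inst_bins[j]]
        chosen = np.where(
            keep, inst_bins[j], rng.choice(others, size=n - 1)
        )
        lohi = np.array([bins.interval(name, b) for b in chosen])
        x[1:, j] = rng.uniform(lohi[:, 0], lohi[:, 1])
    return z, x


def fit_local_surrogate(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    instance: np.ndarray,
    bins: FeatureBins,
    n: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    kernel_width: float | None = None,
    ridge_alpha: float = DEFAULT_RIDGE_ALPHA,
    keep_probability: float = DEFAULT_KEEP_PROBABILITY,
    instance_id: str = "instance",
) -> Explanation:
    """Fit the weighted ridge surrogate around one instance.

    Samples are weighted by exp(−d²/width²) where d is the normalized
    Hamming distance of the interpretable row to the all-ones anchor.
    """
    instance = np.asarray(instance, dtype=float)
    z, x = sample_perturbations(instance, bins, n, seed, keep_probability)
    preds = np.asarray(predict_fn(x), dtype=float)
    if preds.shape != (n,):
        raise ValueError(f"predict_fn must return {n} values, got shape {preds.shape}")
    bad = np.flatnonzero(~np.isfinite(preds))
    if bad.size:
        raise ValueError(f"predict_fn returned non-finite value at sample {int(bad[0])}")
    width = default_kernel_width(len(bins.feature_names)) if kernel_width is None else kernel_width
    d = 1.0 - z.mean(axis=1)
    w = np.exp(-(d**2) / width**2)
    ridge = Ridge(alpha=ridge_alpha)
    ridge.fit(z, preds, sample_weight=w)
    r2 = float(r2_score(preds, ridge.predict(z), sample_weight=w))
    entries = []
    for j, name in enumerate(bins.feature_names):
        b = bins.bin_of(name, instance[j])
        entries.append((bins.label(name, b), name, float(ridge.coef_[j])))
    return Explanation(
        instance_id=instance_id,
        entries=entries,
        intercept=float(ridge.intercept_),
        r2=r2,
        n_samples=n,
        seed=seed,
        kernel_width=float(width),
    )


def render_explanation(e: Explanation, top_k: int) -> str:
    """Human-readable report of the ``top_k`` strongest conditions."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k > len(e.entries):
        warnings.warn(
            f"top_k={top_k} exceeds {len(e.entries)} features; returning all",
            stacklevel=2,
        )
        top_k = len(e.entries)
    lines = [
        f"explanation for {e.instance_id} "
        f"(surrogate R2={e.r2:.3f}, n={e.n_samples}, seed={e.seed})"
    ]
    for label, _feat, weight in e.entries[:top_k]:
        side = "support" if weight >= 0 else "oppose"
        lines.append(f"  {side:7s} {weight:+.4f}  {label}")
    return "\n".join(lines)


def plot_explanation(e: Explanation, top_k: int = 10, path: str | Path | None = None):
    """Horizontal bar chart: green bars support the prediction, red oppose."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = e.entries[: min(top_k, len(e.entries))][::-1]
    labels = [lab for lab, _, _ in top]
    weights = [w for _, _, w in top]
    colors = ["green" if w >= 0 else "red" for w in weights]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(top) + 1))
    ax.barh(labels, weights, color=colors)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("local surrogate weight")
    ax.set_title(e.instance_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
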