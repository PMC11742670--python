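"""Seeded synthetic compound libraries and crisp oracle tables.

``generate_library`` emulates the statistical shape of a screening decision
table: ~40–120 compounds described by ~44 continuous descriptors of which a
small planted subset drives a positive IC50-like response plus noise.  The
returned truth record (planted features, weights, noiseless targets) lets
tests score feature-selection recall and ranking quality directly.

``generate_crisp_table`` builds tiny categorical tables realizing a chosen
indiscernibility partition, the classical-rough-set oracle fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem_io import DescriptorTable, default_descriptor_names
from .fuzzy_rough import FuzzySet

__all__ = ["LibrarySpec", "generate_library", "generate_crisp_table", "plant_redundancy"]

#: Planted effect sizes on the logistic scale; large enough that each
#: relevant descriptor visibly shifts the potency band of a compound.
DEFAULT_EFFECT_WEIGHTS = (3.0, -2.5, 2.0, -1.5, 2.5)


def _feature_names(n_features: int) -> list[str]:
    vocab = default_descriptor_names()
    if n_features <= len(vocab):
        return vocab[:n_features]
    extra = [f"X{k:03d}" for k in range(n_features - len(vocab))]
    return vocab + extra


@dataclass(frozen=True)
class LibrarySpec:
    """Study conditions for one synthetic compound library.

    Defaults mirror the screening-table shape the pipeline assumes: 90
    compounds x 44 descriptors, 5 of them relevant, IC50 spanning
    0.01–100 µg/mL with additive Gaussian noise of 5% of that range.
    """

    n_compounds: int = 90
    n_features: int = 44
    relevant_features: tuple[str, ...] | None = None
    effect_weights: tuple[float, ...] = DEFAULT_EFFECT_WEIGHTS
    noise_sd: float | None = None  # µg/mL; None -> 0.05 * (hi - lo)
    ic50_range: tuple[float, float] = (0.01, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ic50_range
        if not (0 < lo < hi):
            raise ValueError("ic50_range must satisfy 0 < lo < hi")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def resolved_relevant(self) -> tuple[str, ...]:
        names = _feature_names(self.n_features)
        if self.relevant_features is None:
            k = len(self.effect_weights)
            return tuple(names[:k])
        missing = [f for f in self.relevant_features if f not in names]
        if missing:
            raise ValueError(f"relevant features not in table: {', '.join(missing)}")
        return tuple(self.relevant_features)

    def resolved_noise_sd(self) -> float:
        lo, hi = self.ic50_range
        return 0.05 * (hi - lo) if self.noise_sd is None else self.noise_sd


def generate_library(spec: LibrarySpec) -> tuple[DescriptorTable, np.ndarray, dict]:
    """Draw a seeded library: descriptors, noisy IC50 targets, truth record.

    Descriptors are i.i.d. uniform(0, 1).  The latent potency is a logistic
    function of the centred weighted sum of the planted descriptors, mapped
    affinely onto ``ic50_range``; observed targets add Gaussian noise and
    are clipped to stay positive.  With ``noise_sd=0`` the targets equal
    the noiseless truth exactly.
    """
    if spec.n_compounds < 10:
        raise ValueError("n_compounds must be >= 10")
    relevant = spec.resolved_relevant()
    if len(spec.effect_weights) != len(relevant):
        raise ValueError("effect_weights length must match relevant_features")
    names = _feature_names(spec.n_features)
    rng = np.random.default_rng(spec.seed)
    x = rng.uniform(0.0, 1.0, size=(spec.n_compounds, spec.n_features))

    idx = [names.index(f) for f in relevant]
    w = np.asarray(spec.effect_weights, dtype=float)
    z = (x[:, idx] - 0.5) @ w  # centred so the logistic stays responsive
    latent01 = 1.0 / (1.0 + np.exp(-z))
    lo, hi = spec.ic50_range
    noiseless = lo + (hi - lo) * latent01
    sd = spec.resolved_noise_sd()
    noise = rng.normal(0.0, sd, size=spec.n_compounds) if sd > 0 else np.zeros(spec.n_compounds)
    targets = np.maximum(noiseless + noise, 1e-6)

    ids = [f"CPD{k:04d}" for k in range(spec.n_compounds)]
    table = DescriptorTable(ids, names, x)
    truth = {
        "relevant_features": list(relevant),
        "effect_weights": [float(v) for v in w],
        "noiseless_targets": noiseless.tolist(),
        "noise_sd": float(sd),
        "ic50_range": [float(lo), float(hi)],
        "seed": int(spec.seed),
    }
    return table, targets, truth


def generate_crisp_table(
    n_objects: int,
    n_features: int,
    partition: Sequence[Sequence[int]],
    decision: Sequence[Sequence[int]] | None = None,
    seed: int = 0,
) -> tuple[DescriptorTable, list[FuzzySet]]:
    """Categorical 0/1 table realizing a given indiscernibility partition.

    Each partition block gets a distinct ``n_features``-bit code; objects in
    the same block are identical, objects in different blocks differ in at
    least one feature, so the min-similarity relation is exactly the crisp
    block structure.  ``decision`` (a second partition, defaulting to the
    feature partition itself) is returned as crisp 0/1 decision sets.
    """
    if n_objects > 12:
        raise ValueError("generate_crisp_table limited to 12 objects")
    blocks = [tuple(b) for b in partition]
    flat = sorted(i for b in blocks for i in b)
    if flat != list(range(n_objects)):
        raise ValueError(
            f"partition must cover 0..{n_objects - 1} exactly once, got {flat}"
        )
    if 2 ** n_features < len(blocks):
        raise ValueError(
            f"{n_features} binary feature(s) cannot distinguish {len(blocks)} blocks"
        )
    rng = np.random.default_rng(seed)
    codes: set[tuple[int, ...]] = set()
    while len(codes) < len(blocks):
        codes.add(tuple(int(v) for v in rng.integers(0, 2, size=n_features)))
    code_list = sorted(codes)
    values = np.zeros((n_objects, n_features))
    for code, block in zip(code_list, blocks):
        for i in block:
            values[i] = code

    if decision is None:
        decision = blocks
    dsets = []
    for k, dblock in enumerate(decision):
        member = np.zeros(n_objects)
        member[list(dblock)] = 1.0
        dsets.append(FuzzySet(member, label=f"d{k}"))
    ids = [f"x{i + 1}" for i in range(n_objects)]
    names = [f"a{j + 1}" for j in range(n_features)]
    return DescriptorTable(ids, names, values), dsets


def plant_redundancy(
    table: DescriptorTable, feature: str, new_name: str | None = None
) -> DescriptorTable:
    """Append a bit-exact duplicate of ``feature`` under a new name."""
    if feature not in table.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    new_name = new_name or f"{feature}_copy"
    if new_name in table.feature_names:
        raise ValueError(f"name collision: {new_name!r} already present")
    values = np.column_stack([table.values, table.column(feature)])
    return DescriptorTable(
        list(table.compound_ids), list(table.feature_names) + [new_name], values
    )
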