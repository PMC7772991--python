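"""Seedable generator of synthetic sandwich-immunoassay datasets.

The generator emulates the statistical structure the analysis assumes:
triplicate spots with multiplicative lognormal noise, blank and pre-immune
control spots, saturating Langmuir concentration-response, cross-reactive
binding encoded in a relative-affinity matrix R (antibody x antigen, unit
entries for cognate pairs), buffer-only negative controls, heat-treated
controls that ablate the biological signal while a mineral-binding term
survives, and off-chip "relative" antigens that bind an antibody without
reproducing its cognate's cross-reaction pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import DilutionSeries
from .panel import SlideLayout
from .quantify import SPOT_COLUMNS, SpotTable

__all__ = [
    "AntigenUniverse",
    "NoiseModel",
    "BindingModel",
    "SampleSpec",
    "simulate_assay",
    "simulate_crossreactivity_panel",
    "simulate_dilution_series",
    "make_reference_universe",
    "REFERENCE_TOPOLOGY",
]


@dataclass(frozen=True)
class AntigenUniverse:
    """Antigens in play and their relative affinities to the array.

    ``R`` has one row per antibody and one column per antigen, entries in
    [0, 1]; a cognate pair has R = 1 and every on-chip antigen's column has
    exactly one unit entry, at its own antibody. Antigens with
    ``on_chip_cognate = None`` are off-chip relatives.
    """

    antibody_order: tuple[str, ...]
    antigen_ids: tuple[str, ...]
    on_chip_cognate: dict
    R: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.shape != (len(self.antibody_order), len(self.antigen_ids)):
            raise ValueError("R shape must be (n_antibodies, n_antigens)")
        if (R < 0).any() or (R > 1).any():
            raise ValueError("relative affinities must lie in [0, 1]")
        for a, antigen in enumerate(self.antigen_ids):
            cog = self.on_chip_cognate.get(antigen)
            if cog is None:
                continue
            i = self.antibody_order.index(cog)
            col = R[:, a]
            if not math.isclose(col[i], 1.0):
                raise ValueError(f"{antigen}: cognate affinity must be 1")
            if int(np.sum(np.isclose(col, 1.0))) != 1:
                raise ValueError(
                    f"{antigen}: exactly one unit entry allowed per on-chip column"
                )
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "antibody_order", tuple(self.antibody_order))
        object.__setattr__(self, "antigen_ids", tuple(self.antigen_ids))

    def antigen_index(self, antigen_id: str) -> int:
        return self.antigen_ids.index(antigen_id)

    @property
    def on_chip_antigens(self) -> list[str]:
        return [a for a in self.antigen_ids if self.on_chip_cognate.get(a)]

    @property
    def off_chip_antigens(self) -> list[str]:
        return [a for a in self.antigen_ids if not self.on_chip_cognate.get(a)]

    def onchip_affinity_matrix(self) -> np.ndarray:
        """R restricted to on-chip antigens, columns in antibody order.

        This is the ground-truth cross-reactivity matrix a noise-free
        single-immunogen panel should recover.
        """
        cols = []
        for code in self.antibody_order:
            antigen = next(
                a for a in self.antigen_ids if self.on_chip_cognate.get(a) == code
            )
            cols.append(self.R[:, self.antigen_index(antigen)])
        return np.column_stack(cols)


@dataclass(frozen=True)
class NoiseModel:
    """Spot-level noise: multiplicative lognormal, seedable.

    ``replicate_cv`` sets the coefficient of variation of the biological
    term; ``lognormal_sigma``, when given, overrides the sigma used for
    the background and mineral terms. ``mineral_binding_level`` is the
    mean of a non-biological term that survives heat treatment.
    """

    background_mean: float = 100.0
    replicate_cv: float = 0.10
    lognormal_sigma: float | None = None
    mineral_binding_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_mean, self.replicate_cv,
               self.mineral_binding_level) < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def bio_sigma(self) -> float:
        return math.sqrt(math.log1p(self.replicate_cv**2))

    @property
    def bg_sigma(self) -> float:
        if self.lognormal_sigma is not None:
            return self.lognormal_sigma
        return self.bio_sigma


@dataclass(frozen=True)
class BindingModel:
    """Langmuir binding parameters: F(c) = Fmax * c / (c + K) per pair.

    ``fmax`` is a single saturation amplitude shared by all antibodies
    (a.u.); ``k`` the default half-saturation constant (same units as the
    sample concentrations); ``k_overrides`` maps (antibody, antigen) pairs
    to specific K values.
    """

    fmax: float = 20000.0
    k: float = 1.0e4
    k_overrides: dict = field(default_factory=dict)

    def k_for(self, antibody: str, antigen: str) -> float:
        return float(self.k_overrides.get((antibody, antigen), self.k))


@dataclass(frozen=True)
class SampleSpec:
    """What is in the tube: antigen concentrations and heat treatment."""

    concentrations: dict
    heat_treated: bool = False

    def __post_init__(self) -> None:
        bad = {a: c for a, c in self.concentrations.items() if c < 0}
        if bad:
            raise ValueError(f"negative concentrations: {bad}")


def _lognormal_factors(rng, sigma: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative noise; exactly 1 when sigma == 0."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_assay(
    universe: AntigenUniverse,
    sample: SampleSpec,
    layout: SlideLayout | None = None,
    binding: BindingModel | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    field_id: str = "F1",
) -> SpotTable:
    """Simulate one assay field as a raw spot table.

    Each replicate spot of antibody i draws

        intensity = background * e0 + mineral * e1
                    + [unless heat-treated] sum_a R_ia * Fmax * c_a / (c_a + K_ia) * e2

    with independent unit-mean lognormal factors e0, e1, e2 per spot.
    Heat treatment ablates the biological term; background and the
    mineral-binding term survive. Deterministic given the seed.
    """
    layout = layout or SlideLayout()
    binding = binding or BindingModel()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    unknown = set(sample.concentrations) - set(universe.antigen_ids)
    if unknown:
        raise ValueError(f"antigens not in universe: {sorted(unknown)}")

    n_rep = layout.replicate_spots_per_antibody
    rows = []

    def emit(target: str, role: str, bio_mean: float) -> None:
        e0 = _lognormal_factors(rng, noise.bg_sigma, n_rep)
        e1 = _lognormal_factors(rng, noise.bg_sigma, n_rep)
        e2 = _lognormal_factors(rng, noise.bio_sigma, n_rep)
        vals = noise.background_mean * e0 + noise.mineral_binding_level * e1
        if not sample.heat_treated and bio_mean > 0:
            vals = vals + bio_mean * e2
        for r in range(n_rep):
            rows.append(
                {
                    "field_id": field_id,
                    "target": target,
                    "role": role,
                    "replicate": r,
                    "intensity": float(max(vals[r], 0.0)),
                }
            )

    for i, code in enumerate(universe.antibody_order):
        bio = 0.0
        for antigen, c in sample.concentrations.items():
            a = universe.antigen_index(antigen)
            r_ia = universe.R[i, a]
            if r_ia <= 0 or c <= 0:
                continue
            k = binding.k_for(code, antigen)
            bio += r_ia * binding.fmax * c / (c + k)
        emit(code, "antibody", bio)

    emit("BSA", "blank_bsa", 0.0)
    emit("BUFFER", "blank_buffer", 0.0)
    for code in universe.antibody_order:
        emit(code, "preimmune", 0.0)

    return SpotTable(pd.DataFrame(rows, columns=SPOT_COLUMNS))


def simulate_crossreactivity_panel(
    universe: AntigenUniverse,
    layout: SlideLayout | None = None,
    binding: BindingModel | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    saturation_factor: float = 1000.0,
) -> dict[str, SpotTable]:
    """One single-immunogen assay per on-chip cognate, at saturation.

    Tests every antibody-immunogen pair one at a time: the returned map
    ``antibody code -> SpotTable`` feeds matrix construction. At zero
    noise the downstream matrix equals ``universe.onchip_affinity_matrix()``.
    """
    binding = binding or BindingModel()
    noise = noise or NoiseModel()
    base_seed = noise.seed if seed is None else seed
    out = {}
    for n, antigen in enumerate(universe.on_chip_antigens):
        code = universe.on_chip_cognate[antigen]
        c = saturation_factor * binding.k
        out[code] = simulate_assay(
            universe,
            SampleSpec({antigen: c}),
            layout=layout,
            binding=binding,
            noise=noise,
            seed=base_seed + n + 1,
        )
    return out


def simulate_dilution_series(
    universe: AntigenUniverse,
    antibody: str,
    decades=(2, 3, 4, 5, 6),
    binding: BindingModel | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    tracer_mode: str = "single",
    layout: SlideLayout | None = None,
) -> DilutionSeries:
    """Serial dilution of one antibody's cognate immunogen.

    Concentrations are the given decades (10^d). The noise-free threshold
    crossing is available in closed form from (Fmax, K, background,
    multiplier); see :func:`analytic_lod_decade`.
    """
    decades = list(decades)
    if decades != sorted(decades):
        raise ValueError("decades must be ordered")
    binding = binding or BindingModel()
    noise = noise or NoiseModel()
    layout = layout or SlideLayout()
    base_seed = noise.seed if seed is None else seed
    antigen = next(
        a for a in universe.antigen_ids if universe.on_chip_cognate.get(a) == antibody
    )

    from .quantify import estimate_background, summarize_replicates

    concs, signals, bgs = [], [], []
    for n, d in enumerate(decades):
        c = 10.0**d
        table = simulate_assay(
            universe,
            SampleSpec({antigen: c}),
            layout=layout,
            binding=binding,
            noise=noise,
            seed=base_seed * 1000 + n,
        )
        prof = estimate_background(summarize_replicates(table, layout))
        concs.append(c)
        signals.append(float(prof.data.loc[antibody, "F"]))
        bgs.append(prof.background)
    return DilutionSeries(
        antibody_code=antibody,
        concentrations=np.array(concs),
        signals=np.array(signals),
        backgrounds=np.array(bgs),
        tracer_mode=tracer_mode,
    )


def analytic_lod_decade(
    decades,
    binding: BindingModel,
    background: float,
    multiplier: float = 2.5,
) -> float | None:
    """Noise-free threshold crossing of the simulated dilution series.

    Lowest tested decade d with background + Fmax * c/(c+K) > multiplier *
    background at c = 10^d, or None when no decade passes.
    """
    for d in decades:
        c = 10.0**d
        signal = background + binding.fmax * c / (c + binding.k)
        if signal > multiplier * background:
            return float(d)
    return None


# Synthetic 16-antibody topology with 28 directed cross-reactivity links
# (source antibody -> [(target spot, relative affinity), ...]). Lysate/EPS
# partners of the same strain cross-react both ways; the five specific
# antibodies (L2C1, L3C1, L4C1, L7C1, L10C1) have no out-going links and
# are therefore B-type nodes.
REFERENCE_TOPOLOGY = {
    "L1C1": (("L1S2", 0.5), ("L8C1", 0.4), ("L5C1", 0.1)),
    "L1S2": (("L1C1", 0.3), ("L8C1", 0.3)),
    "L8C1": (("L1C1", 0.35), ("L1S2", 0.25), ("L11C1", 0.1)),
    "L6C1": (("L6S2", 0.6), ("L11C1", 0.15), ("L11S2", 0.1)),
    "L6S2": (("L6C1", 0.45), ("L11S2", 0.15)),
    "L11C1": (("L11S2", 0.5), ("L6C1", 0.2), ("L12C1", 0.1)),
    "L11S2": (("L11C1", 0.35), ("L6S2", 0.2)),
    "L12C1": (("L12S2", 0.5), ("L11C1", 0.15)),
    "L12S2": (("L12C1", 0.3), ("L11C1", 0.1), ("L6S2", 0.1)),
    "L5C1": (("L11C1", 0.12), ("L6C1", 0.1), ("L3C1", 0.2)),
    "L9C1": (("L10C1", 0.15), ("L7C1", 0.1)),
}

#: The 16 antibodies retained on the reference array.
REFERENCE_ANTIBODIES = (
    "L1C1", "L2C1", "L3C1", "L4C1", "L5C1", "L6C1", "L7C1", "L8C1",
    "L9C1", "L10C1", "L11C1", "L12C1", "L1S2", "L6S2", "L11S2", "L12S2",
)

# Off-chip relatives: each binds one antibody's spot without reproducing
# the cognate immunogen's cross-reaction pattern, the situation that
# elicits a II.b call downstream.
_OFF_CHIP_RELATIVES = {
    "relative-of-L6": (("L6C1", 0.8),),
    "relative-of-L12": (("L12C1", 0.7),),
    "relative-of-L1": (("L1C1", 0.6), ("L8C1", 0.3)),
}


def make_reference_universe(seed: int = 0, jitter: float = 0.1) -> AntigenUniverse:
    """Universe matching the scale of the real array's antibody graph.

    16 on-chip cognates wired with 28 directed cross-reactivity links
    (including lysate/EPS strain pairs) plus three off-chip relative
    antigens. The link topology is fixed; the seed jitters link weights by
    up to ``jitter`` (relative), keeping them within (0.02, 0.95).
    """
    rng = np.random.default_rng(seed)
    abs_ = REFERENCE_ANTIBODIES
    antigens = [f"antigen-{c}" for c in abs_] + list(_OFF_CHIP_RELATIVES)
    cognate = {f"antigen-{c}": c for c in abs_}
    cognate.update({a: None for a in _OFF_CHIP_RELATIVES})

    R = np.zeros((len(abs_), len(antigens)))
    for a, antigen in enumerate(antigens):
        if cognate[antigen] is not None:
            src = cognate[antigen]
            R[abs_.index(src), a] = 1.0
            links = REFERENCE_TOPOLOGY.get(src, ())
        else:
            links = _OFF_CHIP_RELATIVES[antigen]
        for dst, w in links:
            wj = w * (1.0 + jitter * rng.uniform(-1.0, 1.0))
            R[abs_.index(dst), a] = float(np.clip(wj, 0.02, 0.95))
    return AntigenUniverse(
        antibody_order=abs_,
        antigen_ids=tuple(antigens),
        on_chip_cognate=cognate,
        R=R,
    )
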