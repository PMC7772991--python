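"""Spot quantification: replicate summarisation, background, positivity.

Raw scanner output is modelled as a :class:`SpotTable` of per-spot
fluorescence intensities. Replicate spots for each antibody are summarised
by their median into a per-field :class:`AssayProfile`; blank spots (BSA,
printing buffer, pre-immune serum) give the field background; the
positivity rule declares a spot positive when its signal strictly exceeds
``multiplier`` (default 2.5) times the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import CONTROL_ROLES, SlideLayout

__all__ = [
    "SpotTable",
    "AssayProfile",
    "summarize_replicates",
    "summarize_all_fields",
    "estimate_background",
    "subtract_control",
    "positivity_call",
    "DEFAULT_MULTIPLIER",
    "DEFAULT_CV_LIMIT",
    "DEFAULT_SATURATION_CEILING",
]

DEFAULT_MULTIPLIER = 2.5
DEFAULT_CV_LIMIT = 0.25
#: 16-bit scanner convention.
DEFAULT_SATURATION_CEILING = 65535.0

SPOT_COLUMNS = ["field_id", "target", "role", "replicate", "intensity"]


@dataclass(frozen=True)
class SpotTable:
    """Per-spot intensities for one or more assay fields.

    Columns: ``field_id`` (which replicate field on the slide), ``target``
    (antibody code, or the control identity for blanks), ``role``
    (``antibody`` or one of the control roles), ``replicate`` (index within
    the spot group), ``intensity`` (raw fluorescence, a.u., >= 0).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        if len(self.data) and (self.data["intensity"] < 0).any():
            raise ValueError("spot intensities must be non-negative")
        bad = set(self.data["role"]) - ({"antibody"} | set(CONTROL_ROLES))
        if bad:
            raise ValueError(f"unknown spot roles: {sorted(bad)}")

    @property
    def field_ids(self) -> list:
        return sorted(self.data["field_id"].unique().tolist())

    def field(self, field_id) -> "SpotTable":
        return SpotTable(
            self.data[self.data["field_id"] == field_id].reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class AssayProfile:
    """Summarised fluorescence for one assay field.

    ``data`` is indexed by antibody code with columns ``F`` (median of
    replicates, a.u.), ``cv`` (replicate coefficient of variation),
    ``cv_flag`` and ``saturated`` booleans. ``controls`` holds the
    summarised blank groups; ``background`` the pooled blank median once
    :func:`estimate_background` has run. ``preimmune`` keeps the
    per-antibody pre-immune medians for diagnostics.
    """

    data: pd.DataFrame
    controls: pd.DataFrame
    background: float | None = None
    preimmune: dict = field(default_factory=dict)
    control_provenance: str | None = None

    @property
    def antibodies(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def F(self) -> pd.Series:
        return self.data["F"]

    def f_vector(self, order) -> np.ndarray:
        missing = [a for a in order if a not in self.data.index]
        if missing:
            raise KeyError(f"antibodies absent from profile: {missing}")
        return self.data.loc[list(order), "F"].to_numpy(dtype=float)


def summarize_replicates(
    spot_table: SpotTable,
    layout: SlideLayout | None = None,
    field_id=None,
    cv_limit: float = DEFAULT_CV_LIMIT,
    saturation_ceiling: float = DEFAULT_SATURATION_CEILING,
) -> AssayProfile:
    """Summarise replicate spots of one field into an :class:`AssayProfile`.

    F is the median of the replicate intensities of each antibody — robust
    to a single bad spot in a triplicate. The replicate CV is recorded and
    flagged above ``cv_limit``; a group whose median reaches
    ``saturation_ceiling`` is flagged saturated.

    Raises
    ------
    ValueError
        If a replicate group is incomplete for the layout, or the table
        holds several fields and ``field_id`` is not given.
    """
    layout = layout or SlideLayout()
    df = spot_table.data
    if field_id is None:
        fids = spot_table.field_ids
        if len(fids) != 1:
            raise ValueError(
                f"spot table has fields {fids}; pass field_id to select one"
            )
        field_id = fids[0]
    df = df[df["field_id"] == field_id]
    if df.empty:
        raise ValueError(f"no spots for field {field_id!r}")

    ab = df[df["role"] == "antibody"]
    n_rep = layout.replicate_spots_per_antibody
    rows = {}
    for code, grp in ab.groupby("target", sort=True):
        vals = grp["intensity"].to_numpy(dtype=float)
        if len(vals) != n_rep:
            raise ValueError(
                f"antibody {code!r} in field {field_id!r}: expected "
                f"{n_rep} replicate spots, found {len(vals)}"
            )
        med = float(np.median(vals))
        mean = float(np.mean(vals))
        cv = float(np.std(vals, ddof=0) / mean) if mean > 0 else 0.0
        rows[code] = {
            "F": med,
            "cv": cv,
            "cv_flag": cv > cv_limit,
            "saturated": med >= saturation_ceiling,
        }
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index.name = "antibody"

    ctrl = df[df["role"] != "antibody"]
    crows = []
    preimmune: dict = {}
    for (role, target), grp in ctrl.groupby(["role", "target"], sort=True):
        med = float(np.median(grp["intensity"].to_numpy(dtype=float)))
        crows.append({"role": role, "target": target, "F": med})
        if role == "preimmune":
            preimmune[target] = med
    controls = pd.DataFrame(crows, columns=["role", "target", "F"])
    return AssayProfile(data=data, controls=controls, preimmune=preimmune)


def summarize_all_fields(
    spot_table: SpotTable, layout: SlideLayout | None = None, **kwargs
) -> dict:
    """Summarise every field in the table; returns ``{field_id: profile}``."""
    return {
        fid: summarize_replicates(spot_table, layout, field_id=fid, **kwargs)
        for fid in spot_table.field_ids
    }


def estimate_background(profile: AssayProfile) -> AssayProfile:
    """Pool all blank spot groups into a single background estimate.

    The background B is the median of the summarised intensities of every
    BSA, printing-buffer and pre-immune blank group. Per-antibody
    pre-immune values stay available in ``profile.preimmune`` for
    diagnostics but do not enter B individually.
    """
    blanks = profile.controls[
        profile.controls["role"].isin(["blank_bsa", "blank_buffer", "preimmune"])
    ]
    if blanks.empty:
        raise ValueError("no blank control spots; cannot estimate background")
    b = float(np.median(blanks["F"].to_numpy(dtype=float)))
    return replace(profile, background=b)


def subtract_control(
    sample: AssayProfile,
    control: AssayProfile,
    provenance: str = "buffer_only",
) -> AssayProfile:
    """Subtract a within-chip negative-control profile from a sample profile.

    Used both for the buffer-only control (non-specific fluorescence) and
    for the heat-treated control (500 degC bake destroying organics, so
    residual signal reflects mineral-particle binding). Net values are
    clipped at zero: fluorescence is non-negative. ``provenance`` records
    which control was used (``buffer_only`` or ``heat_treated``).
    """
    if list(sample.data.index) != list(control.data.index):
        raise ValueError("sample and control profiles cover different panels")
    out = sample.data.copy()
    out["F"] = np.maximum(
        sample.data["F"].to_numpy() - control.data["F"].to_numpy(), 0.0
    )
    return replace(sample, data=out, control_provenance=provenance)


def positivity_call(F, B, multiplier: float = DEFAULT_MULTIPLIER):
    """Is the signal positive? True iff ``F > multiplier * B`` (strict).

    Accepts scalars or arrays in ``F``; ties at the threshold are negative.
    """
    if B is None or B <= 0:
        raise ValueError("background must be positive for a positivity call")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    F = np.asarray(F, dtype=float)
    result = F > multiplier * B
    if result.ndim == 0:
        return bool(result)
    return result
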