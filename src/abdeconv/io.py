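"""Plain-text I/O for spot tables, profiles, matrices and reports.

Two spot-table dialects are supported: the package's own TSV
(``field_id, target, role, replicate, intensity``) and a
GenePix-results-like dialect (tab-separated, quoted header block before the
column line, columns ``Block``, ``Row``, ``Column``, ``ID``,
``F635 Median``, ``B635 Median``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import SPOT_COLUMNS, AssayProfile, SpotTable

__all__ = [
    "read_spot_table",
    "write_spot_table",
    "read_profile",
    "write_profile",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_edge_list",
    "write_graphml",
    "read_series_tsv",
    "write_series_tsv",
]

_GENEPIX_REQUIRED = ["Block", "Row", "Column", "ID", "F635 Median", "B635 Median"]

# ID prefixes mapping GenePix-style IDs onto spot roles.
_GENEPIX_ROLES = {
    "BSA": "blank_bsa",
    "BUFFER": "blank_buffer",
    "FRAME": "fluorescent_frame",
}


def read_spot_table(path, dialect: str = "tsv") -> SpotTable:
    """Read a spot table; ``dialect`` is ``tsv`` or ``genepix_like``."""
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "genepix_like":
        return _read_genepix_like(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'genepix_like'")


def _read_tsv(path) -> SpotTable:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return SpotTable(pd.DataFrame(columns=SPOT_COLUMNS))
    header = lines[0].split("\t")
    missing = [c for c in SPOT_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: line 1: missing columns {missing}")
    idx = {c: header.index(c) for c in SPOT_COLUMNS}
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < len(header):
            raise ValueError(f"{path}: line {lineno}: expected "
                             f"{len(header)} fields, got {len(parts)}")
        try:
            rows.append(
                {
                    "field_id": parts[idx["field_id"]],
                    "target": parts[idx["target"]],
                    "role": parts[idx["role"]],
                    "replicate": int(parts[idx["replicate"]]),
                    "intensity": float(parts[idx["intensity"]]),
                }
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return SpotTable(pd.DataFrame(rows, columns=SPOT_COLUMNS))


def _genepix_role(spot_id: str) -> tuple[str, str]:
    """Map a GenePix ID onto (target, role)."""
    sid = spot_id.strip().strip('"')
    if sid.upper() in _GENEPIX_ROLES:
        return sid, _GENEPIX_ROLES[sid.upper()]
    if sid.upper().startswith("PI-"):
        return sid[3:], "preimmune"
    return sid, "antibody"


def _read_genepix_like(path) -> SpotTable:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_i = None
    for i, line in enumerate(lines):
        cols = [c.strip().strip('"') for c in line.split("\t")]
        if all(req in cols for req in _GENEPIX_REQUIRED):
            header_i = i
            header = cols
            break
    if header_i is None:
        raise ValueError(
            f"{path}: no header line with columns {_GENEPIX_REQUIRED}"
        )
    idx = {c: header.index(c) for c in _GENEPIX_REQUIRED}
    rows = []
    rep_counter: dict = {}
    for lineno, line in enumerate(lines[header_i + 1:], start=header_i + 2):
        if not line.strip():
            continue
        parts = [p.strip().strip('"') for p in line.split("\t")]
        if len(parts) < len(header):
            raise ValueError(f"{path}: line {lineno}: expected "
                             f"{len(header)} fields, got {len(parts)}")
        try:
            block = int(parts[idx["Block"]])
            fg = float(parts[idx["F635 Median"]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
        target, role = _genepix_role(parts[idx["ID"]])
        key = (block, target, role)
        rep_counter[key] = rep_counter.get(key, -1) + 1
        rows.append(
            {
                "field_id": f"B{block}",
                "target": target,
                "role": role,
                "replicate": rep_counter[key],
                "intensity": max(fg, 0.0),
            }
        )
    return SpotTable(pd.DataFrame(rows, columns=SPOT_COLUMNS))


def write_spot_table(table: SpotTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def write_profile(profile: AssayProfile, path) -> None:
    """Profile TSV: columns antibody, F, background, cv, flags."""
    out = profile.data.copy()
    out["background"] = profile.background if profile.background is not None else ""
    flags = []
    for _, row in profile.data.iterrows():
        f = []
        if row["cv_flag"]:
            f.append("high_cv")
        if row["saturated"]:
            f.append("saturated")
        flags.append(";".join(f))
    out["flags"] = flags
    out = out[["F", "background", "cv", "flags"]]
    out.to_csv(path, sep="\t", index=True, index_label="antibody")


def read_profile(path) -> AssayProfile:
    df = pd.read_csv(path, sep="\t", index_col="antibody")
    bg = None
    if "background" in df.columns:
        vals = pd.to_numeric(df["background"], errors="coerce").dropna()
        if len(vals):
            bg = float(vals.iloc[0])
    flags = df.get("flags")
    data = pd.DataFrame(
        {
            "F": df["F"].astype(float),
            "cv": df.get("cv", pd.Series(0.0, index=df.index)).fillna(0.0),
        },
        index=df.index,
    )
    if flags is not None:
        fl = flags.fillna("").astype(str)
        data["cv_flag"] = fl.str.contains("high_cv")
        data["saturated"] = fl.str.contains("saturated")
    else:
        data["cv_flag"] = False
        data["saturated"] = False
    controls = pd.DataFrame(columns=["role", "target", "F"])
    return AssayProfile(data=data, controls=controls, background=bg)


def write_matrix_tsv(antibody_order, G, path) -> None:
    pd.DataFrame(np.asarray(G), index=antibody_order, columns=antibody_order).to_csv(
        path, sep="\t", index_label="antibody"
    )


def read_matrix_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix row and column labels differ")
    return list(df.index), df.to_numpy(dtype=float)


def write_edge_list(graph, path) -> None:
    """Directed edge list TSV: src, dst, weight."""
    rows = [
        {"src": u, "dst": v, "weight": d["weight"]}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["src", "dst", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph, path) -> None:
    import networkx as nx

    nx.write_graphml(graph, path)


def write_series_tsv(series_list, path) -> None:
    """Dilution series TSV: antibody, concentration, F, background."""
    rows = []
    for s in series_list:
        for c, f, b in zip(s.concentrations, s.signals, s.backgrounds):
            rows.append(
                {"antibody": s.antibody_code, "concentration": c, "F": f,
                 "background": b, "tracer_mode": s.tracer_mode}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_series_tsv(path) -> list:
    from .calibration import DilutionSeries

    df = pd.read_csv(path, sep="\t")
    out = []
    for (ab, mode), grp in df.groupby(
        ["antibody", df.get("tracer_mode", pd.Series("single", index=df.index))]
    ):
        grp = grp.sort_values("concentration")
        out.append(
            DilutionSeries(
                antibody_code=ab,
                concentrations=grp["concentration"].to_numpy(dtype=float),
                signals=grp["F"].to_numpy(dtype=float),
                backgrounds=grp["background"].to_numpy(dtype=float),
                tracer_mode=mode,
            )
        )
    return out
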