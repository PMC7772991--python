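"""Antibody panel metadata and slide layout.

The default panel describes a sandwich-immunoassay microarray for detecting
perchlorate-reducing bacteria (PRB): polyclonal antibodies raised against
whole-cell lysates (``C1`` codes) or exopolysaccharide fractions (``S2``
codes) of twelve PRB strains, plus four antibodies against the perchlorate
respiration enzymes (perchlorate reductase and chlorite dismutase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PanelEntry",
    "AntibodyPanel",
    "SlideLayout",
    "default_panel",
    "DEFAULT_EXCLUSIONS",
    "CONTROL_ROLES",
]

#: Spot roles that are not antibody capture spots.
CONTROL_ROLES = frozenset(
    {"blank_bsa", "blank_buffer", "preimmune", "fluorescent_frame"}
)

_IMMUNOGEN_KINDS = ("cell_lysate", "eps_fraction", "protein")


@dataclass(frozen=True)
class PanelEntry:
    """One capture antibody on the array.

    Parameters
    ----------
    code : str
        Short antibody identifier, e.g. ``"L6C1"``.
    immunogen_kind : {"cell_lysate", "eps_fraction", "protein"}
        What the antibody was raised against.
    immunogen_name : str
        Free-text description of the immunogen (strain or protein name).
    preimmune_code : str or None
        Identifier of the paired pre-immune serum spot group; required for
        lysate and EPS antibodies, absent for purified-protein antibodies.
    poor_performer : bool
        Metadata flag: antibody known to fail in sandwich format and
        excluded from the cross-reactivity graph.
    """

    code: str
    immunogen_kind: str
    immunogen_name: str
    preimmune_code: str | None = None
    poor_performer: bool = False

    def __post_init__(self) -> None:
        if self.immunogen_kind not in _IMMUNOGEN_KINDS:
            raise ValueError(
                f"immunogen_kind must be one of {_IMMUNOGEN_KINDS}, "
                f"got {self.immunogen_kind!r}"
            )
        if self.immunogen_kind != "protein" and self.preimmune_code is None:
            raise ValueError(
                f"{self.code}: lysate/EPS antibodies need a pre-immune partner"
            )


@dataclass(frozen=True)
class AntibodyPanel:
    """Roster of antibodies printed on the array."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(codes) != len(set(codes)):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate antibody codes in panel: {dup}")

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return any(e.code == code for e in self.entries)

    def __getitem__(self, code: str) -> PanelEntry:
        for e in self.entries:
            if e.code == code:
                return e
        raise KeyError(code)

    def subset(self, codes) -> "AntibodyPanel":
        codes = list(codes)
        missing = [c for c in codes if c not in self]
        if missing:
            raise KeyError(f"codes not in panel: {missing}")
        return AntibodyPanel(tuple(self[c] for c in codes))

    @property
    def strain_eps_entries(self) -> list[PanelEntry]:
        """Entries raised against cell lysates or EPS fractions."""
        return [e for e in self.entries if e.immunogen_kind != "protein"]

    @property
    def protein_entries(self) -> list[PanelEntry]:
        return [e for e in self.entries if e.immunogen_kind == "protein"]


@dataclass(frozen=True)
class SlideLayout:
    """Replicate-field geometry of one slide.

    The default is the 3 x 8 identical-field format: 24 independent assay
    fields per slide, each antibody printed as a triplicate spot pattern,
    with BSA, printing-buffer and pre-immune blanks plus a fluorescent
    frame for grid localisation.
    """

    fields_rows: int = 3
    fields_cols: int = 8
    replicate_spots_per_antibody: int = 3
    control_spot_roles: frozenset = field(
        default_factory=lambda: frozenset(CONTROL_ROLES)
    )

    def __post_init__(self) -> None:
        if self.replicate_spots_per_antibody < 2:
            raise ValueError("need at least 2 replicate spots per antibody")
        if self.fields_rows < 1 or self.fields_cols < 1:
            raise ValueError("field grid dimensions must be positive")
        unknown = set(self.control_spot_roles) - CONTROL_ROLES
        if unknown:
            raise ValueError(f"unknown control roles: {sorted(unknown)}")

    @property
    def n_fields(self) -> int:
        return self.fields_rows * self.fields_cols


# Antibody codes excluded from the cross-reactivity graph for poor
# performance in sandwich format: four EPS antibodies that gave no positive
# signal against their own antigen, and the four anti-protein antibodies.
DEFAULT_EXCLUSIONS = (
    "L2S2", "L3S2", "L4S2", "L8S2",
    "A-PCR", "A-PCRAB", "A-Cld", "A-295",
)

_STRAINS = {
    "L1": "Azospira suillum PS",
    "L2": "Magnetospirillum bellicus VDY",
    "L3": "Ideonella dechloratans",
    "L4": "Dechlorobacter hydrogenophilus LT-1",
    "L5": "Propionivibrio militaris MP",
    "L6": "Dechloromonas agitata CKB",
    "L7": "Magnetospirillum sp. WD",
    "L8": "Azospira sp. ZAP",
    "L9": "Shewanella algae",
    "L10": "Dechloromarinus chlorophilus NSS",
    "L11": "Dechloromonas aromatica RCB",
    "L12": "Arcobacter sp. CAB",
}

# Strains with an EPS-fraction antibody in addition to the lysate antibody.
_EPS_STRAINS = ("L1", "L2", "L3", "L4", "L6", "L8", "L11", "L12")

_PROTEINS = {
    "A-PCR": "perchlorate reductase",
    "A-PCRAB": "perchlorate reductase A/B subunits",
    "A-Cld": "chlorite dismutase",
    "A-295": "protein 295",
}


def default_panel() -> AntibodyPanel:
    """The packaged 24-antibody PRB panel.

    Twelve lysate antibodies (L1C1..L12C1), eight EPS antibodies
    (L1S2..L12S2), and four anti-protein antibodies; lysate/EPS entries
    carry a pre-immune serum partner. Poor performers (the graph
    exclusions) are pre-flagged.
    """
    entries: list[PanelEntry] = []
    for key, strain in _STRAINS.items():
        code = f"{key}C1"
        entries.append(
            PanelEntry(
                code=code,
                immunogen_kind="cell_lysate",
                immunogen_name=strain,
                preimmune_code=f"PI-{code}",
                poor_performer=code in DEFAULT_EXCLUSIONS,
            )
        )
    for key in _EPS_STRAINS:
        code = f"{key}S2"
        entries.append(
            PanelEntry(
                code=code,
                immunogen_kind="eps_fraction",
                immunogen_name=f"{_STRAINS[key]} EPS",
                preimmune_code=f"PI-{code}",
                poor_performer=code in DEFAULT_EXCLUSIONS,
            )
        )
    for code, name in _PROTEINS.items():
        entries.append(
            PanelEntry(
                code=code,
                immunogen_kind="protein",
                immunogen_name=name,
                preimmune_code=None,
                poor_performer=code in DEFAULT_EXCLUSIONS,
            )
        )
    return AntibodyPanel(tuple(entries))
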