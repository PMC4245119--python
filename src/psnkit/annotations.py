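"""Functional-region annotation tables for the ErbB kinase domains.

Author-numbered positions of the canonical regulatory elements (P-loop,
catalytic Lys/Glu pair, alphaC-helix, hinge, gatekeeper, HRD and DFG motifs,
P+1 substrate loop) and the five regulatory-spine (R-spine) residues for
EGFR, ErbB2, ErbB3 and ErbB4, as read off the reference crystal structures
of each kinase.  Values are served verbatim; ranges are inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass

KINASES = ("EGFR", "ErbB2", "ErbB3", "ErbB4")

# region -> kinase -> either (start, end) inclusive range or a set of positions
_REGIONS: dict[str, dict[str, object]] = {
    "p_loop": {"EGFR": (719, 724), "ErbB2": (727, 732),
               "ErbB3": (697, 702), "ErbB4": (700, 705)},
    "catalytic_lysine": {"EGFR": {745}, "ErbB2": {753},
                         "ErbB3": {723}, "ErbB4": {726}},
    "catalytic_ac_glu": {"EGFR": {762}, "ErbB2": {770},
                         "ErbB3": {740}, "ErbB4": {743}},
    "ac_helix": {"EGFR": (751, 769), "ErbB2": (760, 775),
                 "ErbB3": (738, 747), "ErbB4": (733, 749)},
    "hinge": {"EGFR": (792, 796), "ErbB2": (800, 804),
              "ErbB3": (770, 774), "ErbB4": (773, 777)},
    "gatekeeper": {"EGFR": {790}, "ErbB2": {798},
                   "ErbB3": {768}, "ErbB4": {771}},
    "hrd": {"EGFR": (835, 837), "ErbB2": (843, 845),
            "ErbB3": (813, 815), "ErbB4": (816, 818)},
    "dfg": {"EGFR": (855, 857), "ErbB2": (863, 888),
            "ErbB3": (833, 835), "ErbB4": (836, 838)},
    "p1_loop": {"EGFR": (880, 884), "ErbB2": (888, 892),
                "ErbB3": (858, 862), "ErbB4": (861, 865)},
    # alphaC-helix, beta4-strand, HRD-His, DFG-Phe, alphaF-helix Asp
    "r_spine": {"EGFR": {766, 777, 835, 856, 896},
                "ErbB2": {774, 785, 843, 864, 904},
                "ErbB3": {744, 755, 813, 834, 874},
                "ErbB4": {747, 758, 816, 837, 877}},
}

_ALIASES = {
    "p-loop": "p_loop", "ploop": "p_loop",
    "catalytic_k": "catalytic_lysine", "catalytic k": "catalytic_lysine",
    "catalytic_ac_e": "catalytic_ac_glu", "ac-e": "catalytic_ac_glu",
    "alphac_helix": "ac_helix", "ac-helix": "ac_helix",
    "hrd_motif": "hrd", "dfg_motif": "dfg",
    "p+1_loop": "p1_loop", "p+1 loop": "p1_loop",
    "r-spine": "r_spine", "rspine": "r_spine",
    "gatekeeper_residue": "gatekeeper",
}


@dataclass(frozen=True)
class FunctionalAnnotation:
    kinase: str
    region: str
    positions: frozenset
    span: tuple | None  # (start, end) when the region is a contiguous range

    def __contains__(self, resid: int) -> bool:
        return resid in self.positions


def _normalize_region(region: str) -> str:
    key = region.strip().lower().replace(" ", "_").replace("-", "_")
    key = key.replace("α", "a")
    return _ALIASES.get(key, _ALIASES.get(region.strip().lower(), key))


def functional_annotation(kinase: str, region: str) -> FunctionalAnnotation:
    """Look up a functional region of an ErbB-family kinase domain.

    Returns the packaged author-numbered positions verbatim.  Raises
    KeyError listing valid keys on an unknown kinase or region.
    """
    kin = {k.lower(): k for k in KINASES}.get(kinase.strip().lower())
    if kin is None:
        raise KeyError(f"unknown kinase {kinase!r}; valid kinases: {KINASES}")
    reg = _normalize_region(region)
    if reg not in _REGIONS:
        raise KeyError(
            f"unknown region {region!r}; valid regions: {tuple(_REGIONS)}")
    value = _REGIONS[reg][kin]
    if isinstance(value, tuple):
        positions = frozenset(range(value[0], value[1] + 1))
        span = value
    else:
        positions = frozenset(value)
        span = None
    return FunctionalAnnotation(kinase=kin, region=reg,
                                positions=positions, span=span)


def regions() -> tuple:
    """Valid region keys."""
    return tuple(_REGIONS)
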