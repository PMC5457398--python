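"""SRM assay definition for the cetuximab surrogate peptides.

Cetuximab (an IgG1 anti-EGFR monoclonal antibody) is quantified in human
plasma through two proteotypic tryptic peptides located in the variable
(CDR-containing) regions of the Fab fragment: HT4 from the heavy chain and
LT3 from the light chain.  Each peptide is monitored by three SRM
transitions in two isotope channels: *light* (the endogenous analyte
peptide released by trypsin digestion) and *heavy* (the co-eluting
[13C6;15N4]-labelled internal-standard peptide spiked before digestion).
One transition per channel is the quantifier; the other two are qualifiers
monitored only to confirm identity via relative ion ratios.

The assay is a fixed dictionary of transitions; nothing here predicts
transitions from sequence.  It can be round-tripped through a small YAML
schema, and the canonical definition ships with the package
(``data/cetuximab_assay.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable

import yaml

__all__ = [
    "TransitionDef",
    "PeptideAssay",
    "build_cetuximab_assay",
    "validate_assay",
    "assay_to_dict",
    "assay_from_dict",
    "save_assay",
    "load_assay",
    "LABEL_MASS_DA",
]

#: Mass added by the [13C6;15N4] label on the C-terminal arginine (Da).
LABEL_MASS_DA = 10.0

LIGHT = "light"
HEAVY = "heavy"


@dataclass(frozen=True)
class TransitionDef:
    """One precursor→product SRM transition of a surrogate peptide."""

    peptide_id: str
    channel: str  # "light" | "heavy"
    precursor_mz: float
    precursor_charge: int
    product_mz: float
    product_label: str
    collision_energy: float  # eV
    expected_rt: float  # minutes
    is_quantifier: bool = False


@dataclass
class PeptideAssay:
    """A surrogate peptide with its light and heavy transition sets."""

    peptide_id: str
    sequence: str
    average_mass: float  # Da, unlabelled peptide
    transitions: list[TransitionDef] = field(default_factory=list)

    def channel_transitions(self, channel: str) -> list[TransitionDef]:
        return [t for t in self.transitions if t.channel == channel]

    def quantifier(self, channel: str) -> TransitionDef:
        quants = [t for t in self.channel_transitions(channel) if t.is_quantifier]
        if len(quants) != 1:
            raise ValueError(
                f"{self.peptide_id}/{channel}: expected exactly one quantifier, "
                f"found {len(quants)}"
            )
        return quants[0]

    def qualifiers(self, channel: str) -> list[TransitionDef]:
        return [t for t in self.channel_transitions(channel) if not t.is_quantifier]


def _transitions(peptide_id, channel, precursor_mz, charge, products, ce, rt):
    """Build the three transitions of one channel; first product is quantifier."""
    out = []
    for i, (product_mz, label) in enumerate(products):
        out.append(
            TransitionDef(
                peptide_id=peptide_id,
                channel=channel,
                precursor_mz=precursor_mz,
                precursor_charge=charge,
                product_mz=product_mz,
                product_label=label,
                collision_energy=ce,
                expected_rt=rt,
                is_quantifier=(i == 0),
            )
        )
    return out


def build_cetuximab_assay() -> list[PeptideAssay]:
    """Return the canonical cetuximab assay: HT4 and LT3, 3+3 transitions each.

    HT4 (heavy chain): GLEWLGVIWSGGNTDYNTPFTSR, triply charged precursor at
    857.6 (light) / 860.9 (heavy), CE 16 eV, eluting at 8.8 min.  LT3 (light
    chain): ASQSIGTNIHWYQQR, precursor 597.2 / 600.6 (z=3), CE 15 eV, 3.6 min.
    The first listed product ion of each channel is the quantifier; the other
    two are monitored for identity verification.
    """
    ht4 = PeptideAssay(
        peptide_id="HT4",
        sequence="GLEWLGVIWSGGNTDYNTPFTSR",
        average_mass=2570.8,
        transitions=(
            _transitions(
                "HT4", LIGHT, 857.6, 3,
                [(908.6, "y16^2+"), (851.6, "y15^2+"), (759.0, "y14^2+")],
                ce=16.0, rt=8.8,
            )
            + _transitions(
                "HT4", HEAVY, 860.9, 3,
                [(913.6, "y16^2+"), (857.2, "y15^2+"), (764.0, "y14^2+")],
                ce=16.0, rt=8.8,
            )
        ),
    )
    lt3 = PeptideAssay(
        peptide_id="LT3",
        sequence="ASQSIGTNIHWYQQR",
        average_mass=1788.9,
        transitions=(
            _transitions(
                "LT3", LIGHT, 597.2, 3,
                [(652.0, "y10^2+"), (708.6, "y11^2+"), (752.2, "y12^2+")],
                ce=15.0, rt=3.6,
            )
            + _transitions(
                "LT3", HEAVY, 600.6, 3,
                [(657.0, "y10^2+"), (713.6, "y11^2+"), (757.2, "y12^2+")],
                ce=15.0, rt=3.6,
            )
        ),
    )
    return [ht4, lt3]


def validate_assay(assays: Iterable[PeptideAssay]) -> list[str]:
    """Check every assay invariant; return human-readable violations.

    Reports rather than raises so callers can surface all problems at once.
    An empty list means the assay definition is internally consistent.
    """
    violations: list[str] = []
    for pep in assays:
        for t in pep.transitions:
            tag = f"{pep.peptide_id}/{t.channel}/{t.product_mz}"
            if t.precursor_charge < 1:
                violations.append(f"{tag}: precursor charge {t.precursor_charge} < 1")
            if t.precursor_mz <= 0 or t.product_mz <= 0:
                violations.append(f"{tag}: non-positive m/z")
            if t.expected_rt <= 0:
                violations.append(f"{tag}: non-positive expected RT")
        for channel in (LIGHT, HEAVY):
            trans = pep.channel_transitions(channel)
            if len(trans) != 3:
                violations.append(
                    f"{pep.peptide_id}/{channel}: expected 3 transitions, found {len(trans)}"
                )
            n_quant = sum(t.is_quantifier for t in trans)
            if n_quant != 1:
                violations.append(
                    f"{pep.peptide_id}/{channel}: expected exactly one quantifier, "
                    f"found {n_quant}"
                )
        lights = pep.channel_transitions(LIGHT)
        heavies = pep.channel_transitions(HEAVY)
        for t in lights:
            if not any(h.expected_rt == t.expected_rt for h in heavies):
                violations.append(
                    f"{pep.peptide_id}: light transition {t.product_mz} has no heavy "
                    f"partner at RT {t.expected_rt}"
                )
        if lights and heavies:
            if max(h.precursor_mz for h in heavies) <= max(t.precursor_mz for t in lights):
                violations.append(
                    f"{pep.peptide_id}: heavy precursor m/z not above light "
                    f"(isotope label should add mass)"
                )
    return violations


# ---------------------------------------------------------------------------
# serialization

def assay_to_dict(assays: Iterable[PeptideAssay]) -> dict:
    return {
        "peptides": [
            {
                "peptide_id": p.peptide_id,
                "sequence": p.sequence,
                "average_mass": p.average_mass,
                "transitions": [asdict(t) for t in p.transitions],
            }
            for p in assays
        ]
    }


def assay_from_dict(data: dict) -> list[PeptideAssay]:
    assays = []
    for p in data["peptides"]:
        assays.append(
            PeptideAssay(
                peptide_id=p["peptide_id"],
                sequence=p["sequence"],
                average_mass=float(p["average_mass"]),
                transitions=[TransitionDef(**t) for t in p["transitions"]],
            )
        )
    return assays


def save_assay(assays: Iterable[PeptideAssay], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(assay_to_dict(assays), fh, sort_keys=False)


def load_assay(path=None) -> list[PeptideAssay]:
    """Load an assay definition; with no path, the packaged cetuximab default."""
    if path is None:
        ref = resources.files("srmtdm").joinpath("data/cetuximab_assay.yaml")
        with ref.open("r") as fh:
            return assay_from_dict(yaml.safe_load(fh))
    with open(path) as fh:
        return assay_from_dict(yaml.safe_load(fh))
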