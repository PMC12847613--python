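"""Literature-derived model constants.

Everything that is not one of the ten fitted parameters and not a measured
patient quantity lives here: receptor-ligand kinetics, per-organ serum flows
and permeability-surface-area products, reference organ volumes, the kidney
reabsorption/transit constants, and the physical half-lives of the two
nuclides.  The values are editable defaults in the style of a whole-body
ligand-kinetics model; every quantitative test in the package runs against
synthetic data generated with these same constants, so no result depends on
their absolute accuracy.

Units in this file follow the conventions of the physiology literature
(rates per second, flows L/min, volumes L for a 73-kg reference adult);
the model core converts to its internal minute-based units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

AVOGADRO = 6.02214076e23

#: organs with only vascular + interstitial spaces (no SSTR2 binding)
NONSPECIFIC_ORGANS = ("heart", "bone", "fat", "lung", "skin", "brain")

#: SSTR2-expressing organs with receptor-bound/endosomal/lysosomal spaces
#: (the kidney has its own extended submodel and is handled separately)
SPECIFIC_ORGANS = (
    "gi",
    "liver",
    "spleen",
    "muscle_fat",
    "red_marrow",
    "prostate",
    "adrenals",
    "rest_of_body",
    "tumour1",
    "tumour2",
    "tumour_liver",
    "tumour_rob",
)

TUMOUR_REGIONS = ("tumour1", "tumour2", "tumour_liver", "tumour_rob")

#: reference body weight the per-organ volumes/flows below refer to
REFERENCE_BODY_WEIGHT_KG = 73.0


@dataclass
class OrganConstants:
    """Fixed anatomical/physiological description of one organ."""

    volume_l: float  # total organ volume at reference body weight; None -> patient-measured
    serum_flow_l_min: float  # plasma flow at reference body weight
    ps_l_min: float  # capillary permeability-surface-area product for the peptide
    vascular_fraction: float = 0.05
    interstitial_fraction: float = 0.15
    receptor_density_nmol_l: float = 0.0  # literature density for non-fitted organs


@dataclass
class NuclideConstants:
    half_life_min: float

    @property
    def decay_constant_per_min(self) -> float:
        import math

        return math.log(2.0) / self.half_life_min

    @property
    def mbq_per_nmol(self) -> float:
        """Activity of 1 nmol of carrier-free nuclide (MBq)."""
        lam_per_s = self.decay_constant_per_min / 60.0
        return lam_per_s * AVOGADRO * 1e-9 / 1e6


@dataclass
class LiteratureConstants:
    """Container for every non-fitted model constant.

    ``organs`` covers the fixed-anatomy organs; patient-measured volumes
    (kidneys, spleen, liver, tumours) carry ``volume_l = 0`` here and are
    supplied by :class:`~tacpredict.physiology.PatientPhysiology`.
    """

    kd_nmol_l: float = 1.5
    kon_per_nmol_l_per_s: float = 8.0e-3
    internalization_rate_per_s: float = 3.0e-3  # agonist-driven SSTR2 internalization, t1/2 ~ 4 min
    #: endosomal recycling back to the interstitial space; competes with the
    #: fitted sorting rate, so sorting sets the lysosomal retention fraction
    endosomal_recycling_rate_per_s: float = 1.0e-2
    kidney_reabsorption_fraction: float = 0.03
    collecting_duct_rate_per_s: float = 5.0e-3  # pelvis/ureter transit, minutes
    kidney_nonspecific_on_per_s: float = 2.0e-6
    kidney_nonspecific_off_per_s: float = 2.0e-6
    serum_volume_l_per_kg: float = 0.0435
    venous_fraction: float = 2.0 / 3.0
    #: tumour PS product as a fraction of the (fitted) tumour serum flow;
    #: deliberately small so that uptake of a receptor-saturating dose is
    #: delivery-limited and the tumour flow parameter is identifiable
    tumour_ps_per_flow: float = 0.008
    organs: dict[str, OrganConstants] = field(default_factory=lambda: _default_organs())
    nuclides: dict[str, NuclideConstants] = field(
        default_factory=lambda: {
            "ga68": NuclideConstants(half_life_min=67.71),
            "lu177": NuclideConstants(half_life_min=9563.0),
        }
    )

    def validate(self) -> None:
        if not (0.0 <= self.kidney_reabsorption_fraction <= 1.0):
            raise ValueError("kidney_reabsorption_fraction must be in [0, 1]")
        for name in ("kd_nmol_l", "kon_per_nmol_l_per_s", "internalization_rate_per_s",
                     "collecting_duct_rate_per_s", "serum_volume_l_per_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for organ, oc in self.organs.items():
            if organ.startswith("tumour"):
                continue  # tumour flow/PS derive from the fitted flow parameter
            if oc.serum_flow_l_min <= 0 or oc.ps_l_min < 0:
                raise ValueError(f"non-positive flow/PS for organ {organ!r}")
        for nid, nc in self.nuclides.items():
            if nc.half_life_min <= 0:
                raise ValueError(f"non-positive half-life for nuclide {nid!r}")

    # -- serialisation ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LiteratureConstants":
        payload = json.loads(Path(path).read_text())
        payload["organs"] = {k: OrganConstants(**v) for k, v in payload["organs"].items()}
        payload["nuclides"] = {k: NuclideConstants(**v) for k, v in payload["nuclides"].items()}
        obj = cls(**payload)
        obj.validate()
        return obj


def _default_organs() -> dict[str, OrganConstants]:
    """Reference-adult organ table (73 kg).

    Serum (plasma) flows sum to ~3.4 L/min, consistent with a cardiac output
    of ~5.6 L/min at a haematocrit of ~0.40.  PS products are a fixed fraction
    of flow for ordinary capillary beds; the brain gets a near-zero PS
    (blood-brain barrier excludes the peptide).
    """

    def oc(v, q, ps_frac=0.2, fv=0.05, fi=0.15, rd=0.0, ps=None):
        return OrganConstants(
            volume_l=v,
            serum_flow_l_min=q,
            ps_l_min=ps if ps is not None else ps_frac * q,
            vascular_fraction=fv,
            interstitial_fraction=fi,
            receptor_density_nmol_l=rd,
        )

    return {
        # non-specific organs: vascular + interstitial only
        "heart": oc(0.31, 0.12),
        "bone": oc(5.0, 0.10, fv=0.04, fi=0.10),
        "fat": oc(12.0, 0.15, fv=0.02, fi=0.15),
        "lung": oc(0.50, 0.08, fv=0.10),
        "skin": oc(2.6, 0.17),
        "brain": oc(1.45, 0.35, fi=0.10, ps=0.002),
        # SSTR2-expressing organs; receptor densities for organs that are not
        # among the ten fitted parameters come from the model lineage
        "gi": oc(1.30, 0.55, rd=2.0),
        "liver": oc(0.0, 0.45, fv=0.10),  # volume patient-measured
        "spleen": oc(0.0, 0.08, fv=0.20),  # volume patient-measured
        "muscle_fat": oc(28.0, 0.38, fi=0.12),
        "red_marrow": oc(1.1, 0.10, rd=1.0),
        "prostate": oc(0.016, 0.010, rd=2.0),
        "adrenals": oc(0.014, 0.010, rd=10.0),
        "rest_of_body": oc(-1.0, 0.30, rd=0.5),  # volume derived from body size
        "kidneys": oc(0.0, 0.55, fv=0.10),  # volume patient-measured
        # tumour lesions: volumes patient-measured, flow fitted; PS derived
        "tumour1": oc(0.0, -1.0, fv=0.10, fi=0.30, ps=0.0),
        "tumour2": oc(0.0, -1.0, fv=0.10, fi=0.30, ps=0.0),
        "tumour_liver": oc(0.0, -1.0, fv=0.10, fi=0.30, ps=0.0),
        "tumour_rob": oc(0.0, -1.0, fv=0.10, fi=0.30, ps=0.0),
    }


DEFAULT_CONSTANTS = LiteratureConstants()
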