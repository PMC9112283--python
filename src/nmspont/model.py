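"""Domain types shared across the package.

The objects here describe a single neuromast — the rosette-shaped
lateral-line organ of mechanosensory hair cells, surrounding supporting
cells and contacting cholinergic efferent terminals — together with the
generative parameters of its spontaneous calcium activity and the ROI /
trace containers used on the analysis side.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: ΔF/F0 value below which fluorescence fluctuation is treated as noise.
#: Signals must exceed 10% ΔF/F0 to count as true indicator signal.
DFF_THRESHOLD = 0.10

CELL_TYPES = ("hair_cell", "supporting_cell", "efferent_terminal")

#: Compartments carrying an activity trace, by cell type.  Hair cells have
#: a cytosolic soma, an apical mechanosensory (hair) bundle and a basal
#: ribbon presynapse; supporting cells are read at the soma; efferent
#: neurons are read at their terminal boutons.
COMPARTMENTS_BY_TYPE: Mapping[str, tuple[str, ...]] = {
    "hair_cell": ("soma", "bundle", "presynapse"),
    "supporting_cell": ("soma",),
    "efferent_terminal": ("terminal",),
}

#: Developmental staging of hair cells by kinocilium height (µm).
STAGES = ("early", "intermediate", "late", "mature")
KINOCILIUM_HEIGHT_UM: Mapping[str, str] = {
    "early": "not detectable",
    "intermediate": "1-10 um",
    "late": ">10 <18 um",
    "mature": ">18 um",
}

#: Default ROI diameters (µm) by role.
ROI_DIAMETER_UM: Mapping[str, float] = {
    "soma_hair_cell": 5.0,      # hair-cell base
    "bundle": 2.0,              # hair bundle
    "presynapse": 2.0,
    "terminal": 2.0,            # efferent terminal
    "soma_supporting_cell": 3.0,
}


def default_roi_diameter_um(cell_type: str, compartment: str) -> float:
    if compartment == "soma":
        return ROI_DIAMETER_UM[f"soma_{cell_type}"]
    return ROI_DIAMETER_UM.get(compartment, 3.0)


@dataclass
class EventParams:
    """Parameters of one compartment's spontaneous transient process.

    rate_per_s
        Homogeneous Poisson event rate λ (events / s).
    amplitude_dff
        Peak ΔF/F0 of a single transient, A.
    duration_s
        True time a single transient spends above ΔF/F0 = 0.10, D.
    rise_s
        Linear rise time of the transient.
    baseline_f
        Resting fluorescence, arbitrary units.
    noise_sd_dff
        SD of additive Gaussian noise on the ΔF/F0 scale.
    noise_variance_ratio
        If set, overrides ``noise_sd_dff``: the noise variance is this
        fraction of the realized activity-signal variance (used for the
        efferent synchrony condition where the noise level is specified
        relative to signal).
    """

    rate_per_s: float
    amplitude_dff: float
    duration_s: float
    rise_s: float = 3.0
    baseline_f: float = 100.0
    noise_sd_dff: float = 0.01
    noise_variance_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rate_per_s < 0:
            raise ValueError(f"event rate must be >= 0, got {self.rate_per_s}")
        if self.rate_per_s > 0 and self.amplitude_dff <= DFF_THRESHOLD:
            raise ValueError(
                "amplitude_dff must exceed the detection threshold "
                f"{DFF_THRESHOLD} when the event rate is positive "
                f"(got {self.amplitude_dff})"
            )
        if self.duration_s <= self.rise_s:
            raise ValueError("duration_s must exceed rise_s")
        if self.baseline_f <= 0:
            raise ValueError("baseline_f must be positive")
        if self.noise_sd_dff < 0:
            raise ValueError("noise_sd_dff must be >= 0")


@dataclass
class CellSpec:
    """One cell and the event parameters of each of its compartments.

    ``position_um`` is (x, y, z) in µm with z = 0 at the apical-most
    imaging plane.
    """

    cell_id: str
    cell_type: str
    position_um: tuple[float, float, float]
    compartments: dict[str, EventParams]
    stage: str = "intermediate"

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        expected = set(COMPARTMENTS_BY_TYPE[self.cell_type])
        got = set(self.compartments)
        # The wave preset uses positional sub-ROIs instead of anatomical
        # compartments, so only enforce the anatomical set when the
        # compartment names are anatomical.
        if got & {"soma", "bundle", "presynapse", "terminal"} and got != expected:
            raise ValueError(
                f"{self.cell_type} must have compartments {sorted(expected)}, "
                f"got {sorted(got)}"
            )

    @property
    def kinocilium_height(self) -> str:
        return KINOCILIUM_HEIGHT_UM[self.stage]


@dataclass
class ConditionSpec:
    """A pharmacological or genetic manipulation as a parameter transform.

    ``rate_multipliers`` maps (cell_type, compartment) to a multiplier on
    the Poisson event rate; missing keys mean "unchanged".
    ``baseline_multipliers`` maps cell_type to a multiplier on resting
    fluorescence. ``phi_override`` maps a cell type to a replacement
    shared-variance fraction for coupling groups made of that cell type.
    """

    name: str
    rate_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_multipliers: dict[str, float] = field(default_factory=dict)
    phi_override: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, mult in self.rate_multipliers.items():
            if mult < 0:
                raise ValueError(f"rate multiplier for {key} must be >= 0")
        for ct, phi in self.phi_override.items():
            if not 0.0 <= phi <= 1.0:
                raise ValueError(f"phi override for {ct} must be in [0, 1]")

    def rate_multiplier(self, cell_type: str, compartment: str) -> float:
        return self.rate_multipliers.get((cell_type, compartment), 1.0)


Member = tuple[str, str]  # (cell_id, compartment)


@dataclass
class CouplingGroup:
    """A set of compartment traces sharing a common-source fraction φ."""

    members: tuple[Member, ...]
    phi: float


@dataclass
class NeuromastModel:
    """Ground-truth description of one simulated neuromast recording."""

    neuromast_id: str
    cells: list[CellSpec]
    coupling: list[tuple[Member, Member, float]]
    recording_s: float
    frame_interval_s: float
    seed: int
    condition: Optional[ConditionSpec] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.recording_s <= 0:
            raise ValueError("recording_s must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell ids must be unique")
        for a, b, phi in self.coupling:
            if not 0.0 <= phi <= 1.0:
                raise ValueError(f"phi must be in [0, 1], got {phi} for {a}-{b}")

    @property
    def n_frames(self) -> int:
        return int(round(self.recording_s / self.frame_interval_s))

    def cell(self, cell_id: str) -> CellSpec:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)

    def members(self) -> list[Member]:
        """All (cell_id, compartment) trace identities, in model order."""
        out: list[Member] = []
        for c in self.cells:
            for comp in c.compartments:
                out.append((c.cell_id, comp))
        return out

    def coupling_groups(self, atol: float = 1e-9) -> list[CouplingGroup]:
        """Partition coupled members into groups with a single φ each.

        The pairwise list is the stored representation; generation needs
        the group view (one shared source per group). Components whose
        pairwise φ values disagree beyond ``atol`` are rejected.
        """
        parent: dict[Member, Member] = {}

        def find(x: Member) -> Member:
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: Member, b: Member) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for a, b, _phi in self.coupling:
            union(a, b)
        comp_members: dict[Member, list[Member]] = {}
        for m in parent:
            comp_members.setdefault(find(m), []).append(m)
        comp_phi: dict[Member, float] = {}
        for a, b, phi in self.coupling:
            root = find(a)
            if root in comp_phi and not math.isclose(
                comp_phi[root], phi, abs_tol=atol
            ):
                raise ValueError(
                    "coupling pairs within one connected group must share phi"
                )
            comp_phi.setdefault(root, phi)
        member_order = {m: i for i, m in enumerate(self.members())}
        groups = []
        for root, members in comp_members.items():
            members.sort(key=member_order.__getitem__)
            groups.append(CouplingGroup(tuple(members), comp_phi[root]))
        groups.sort(key=lambda g: member_order[g.members[0]])
        return groups


@dataclass
class Roi:
    """A circular region of interest on a projected plane."""

    neuromast_id: str
    cell_id: str
    cell_type: str
    compartment: str
    x_px: float
    y_px: float
    diameter_um: float

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("ROI diameter must be positive")


@dataclass
class Trace:
    """Per-ROI fluorescence trace with erosion baseline and ΔF/F0.

    Invariants: equal lengths; F0 <= F pointwise (erosion of the raw
    trace) hence dff >= 0; F0 > 0.
    """

    roi: Optional[Roi]
    F: np.ndarray
    F0: np.ndarray
    dff: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        if not (len(self.F) == len(self.F0) == len(self.dff)):
            raise ValueError("F, F0 and dff must have equal length")
        if np.any(self.F0 <= 0):
            raise ValueError("F0 must be positive everywhere")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.F)) * self.frame_interval_s
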