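"""Ground-truth generator for spontaneous neuromast calcium activity.

Emulates the statistical structure of diSPIM GCaMP6s/RGECO1 recordings of
zebrafish lateral-line neuromasts: sparse spontaneous transients in hair
cells, supporting cells and efferent terminals, population coupling with a
configurable shared-variance fraction φ, pharmacology/genotype condition
switches, and optional volumetric movie rendering with Poisson shot noise
and rigid drift.

The transient template is a linear rise followed by an exponential decay
whose time constant is solved from the configured *true duration* D —
defined as the time a single transient spends above ΔF/F0 = 0.10 — so
that duration recovery by the analysis pipeline is well defined.

Population coupling uses a standardized shared-source mixture: a common
transient train and per-trace private trains — independent realizations
of the same rate-λ process — are rendered, standardized, and combined as

    z_i = sqrt(φ) * c~  +  sqrt(1−φ) * e_i~

so the expected pairwise Pearson correlation of the noiseless activity is
exactly φ.  The cost of the exact correlation contract is that within a
coupled population, shared events carry amplitude ≈ √φ·A and private
events ≈ √(1−φ)·A, and each trace superposes both trains.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    COMPARTMENTS_BY_TYPE,
    DFF_THRESHOLD,
    CellSpec,
    ConditionSpec,
    CouplingGroup,
    EventParams,
    Member,
    NeuromastModel,
    Roi,
    default_roi_diameter_um,
)

__all__ = [
    "decay_tau",
    "transient_profile",
    "sample_event_train",
    "activity_from_events",
    "render_trace",
    "couple_traces",
    "build_preset",
    "apply_condition",
    "generate_traces",
    "render_movie",
    "write_fixture_bundle",
    "default_rois",
    "PRESET_NAMES",
    "CONDITION_NAMES",
    "SimTrace",
    "TraceBundle",
]

#: Default voxel spacing (z, y, x) in µm, matching 1 µm z-steps and
#: 325 nm pixels of the fast-acquisition mode.
DEFAULT_VOXEL_SPACING_UM = (1.0, 0.325, 0.325)


# --------------------------------------------------------------------------
# transient template
# --------------------------------------------------------------------------

def decay_tau(
    amplitude_dff: float,
    duration_s: float,
    rise_s: float,
    theta: float = DFF_THRESHOLD,
) -> float:
    """Decay constant giving a true above-``theta`` time of ``duration_s``.

    The template rises linearly to ``amplitude_dff`` over ``rise_s`` and
    decays exponentially.  It crosses ``theta`` upward at
    ``rise_s * theta / A`` and downward at ``rise_s + tau * ln(A/theta)``;
    the decay constant is solved so the difference equals ``duration_s``.
    """
    A = amplitude_dff
    if A <= theta:
        raise ValueError(
            f"amplitude {A} must exceed threshold {theta}: decay constant "
            "is undefined for transients that never cross the threshold"
        )
    tau = (duration_s - rise_s * (1.0 - theta / A)) / math.log(A / theta)
    if tau <= 0:
        raise ValueError(
            f"duration {duration_s}s too short for rise {rise_s}s at "
            f"amplitude {A}"
        )
    return tau


def transient_profile(
    t: np.ndarray, amplitude_dff: float, rise_s: float, tau: float
) -> np.ndarray:
    """Single-transient ΔF/F0 profile at times ``t`` (s, event start = 0)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= 0) & (t < rise_s)
    out[rising] = amplitude_dff * t[rising] / rise_s
    decaying = t >= rise_s
    out[decaying] = amplitude_dff * np.exp(-(t[decaying] - rise_s) / tau)
    return out


def _template_integrals(rise_s: float, tau: float) -> tuple[float, float]:
    # int h, int h^2 of the unit-amplitude template over [0, inf)
    return rise_s / 2.0 + tau, rise_s / 3.0 + tau / 2.0


def sample_event_train(
    rate_per_s: float, recording_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Event times of a homogeneous Poisson process on [0, recording_s)."""
    if rate_per_s < 0:
        raise ValueError(f"event rate must be >= 0, got {rate_per_s}")
    if recording_s <= 0:
        raise ValueError("recording_s must be positive")
    count = rng.poisson(rate_per_s * recording_s)
    return np.sort(rng.uniform(0.0, recording_s, size=count))


def activity_from_events(
    events: np.ndarray,
    amplitude_dff: float,
    rise_s: float,
    tau: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Sum of transient templates at ``t_grid``; overlaps add."""
    t_grid = np.asarray(t_grid, dtype=float)
    a = np.zeros_like(t_grid)
    if len(events) == 0:
        return a
    support = rise_s + tau * math.log(1e6)  # template < 1e-6 * A beyond this
    uniform_1d = (
        t_grid.ndim == 1
        and len(t_grid) > 1
        and np.allclose(np.diff(t_grid), t_grid[1] - t_grid[0])
    )
    if uniform_1d:
        for te in np.asarray(events, dtype=float):
            lo = np.searchsorted(t_grid, te)
            hi = np.searchsorted(t_grid, te + support)
            if lo < hi:
                a[lo:hi] += transient_profile(
                    t_grid[lo:hi] - te, amplitude_dff, rise_s, tau
                )
    else:
        for te in np.asarray(events, dtype=float):
            a += transient_profile(t_grid - te, amplitude_dff, rise_s, tau)
    return a


# --------------------------------------------------------------------------
# trace rendering
# --------------------------------------------------------------------------

@dataclass
class SimTrace:
    """One simulated raw-fluorescence trace with its ground truth."""

    F: np.ndarray
    activity: np.ndarray  # noiseless ΔF/F0-scale activity signal
    event_times_common: np.ndarray
    event_times_private: np.ndarray
    params: EventParams
    frame_interval_s: float

    @property
    def event_times(self) -> np.ndarray:
        return np.sort(
            np.concatenate([self.event_times_common, self.event_times_private])
        )


def _noise_sd(params: EventParams, activity: np.ndarray) -> float:
    if params.noise_variance_ratio is not None:
        v = float(np.var(activity))
        return math.sqrt(params.noise_variance_ratio * v)
    return params.noise_sd_dff


def render_trace(
    events: np.ndarray,
    params: EventParams,
    frame_interval_s: float,
    recording_s: float,
    rng: np.random.Generator,
) -> SimTrace:
    """Render raw fluorescence F(t) from an event train.

    F(t) = baseline * (1 + a(t)) + baseline * eps(t) with a(t) the sum of
    calibrated transients and eps Gaussian noise on the ΔF/F0 scale.
    """
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    n = int(round(recording_s / frame_interval_s))
    t = np.arange(n) * frame_interval_s
    events = np.asarray(events, dtype=float)
    if len(events) > 0:
        tau = decay_tau(params.amplitude_dff, params.duration_s, params.rise_s)
        a = activity_from_events(
            events, params.amplitude_dff, params.rise_s, tau, t
        )
    else:
        a = np.zeros(n)
    sd = _noise_sd(params, a)
    F = params.baseline_f * (1.0 + a)
    if sd > 0:
        F = F + params.baseline_f * rng.normal(0.0, sd, size=n)
    return SimTrace(F, a, np.empty(0), events, params, frame_interval_s)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = float(np.std(x))
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - float(np.mean(x))) / sd


def _coupled_activities(
    params: EventParams,
    phi: float,
    member_rates: Sequence[float],
    frame_interval_s: float,
    recording_s: float,
    common_rng: np.random.Generator,
    member_rngs: Sequence[np.random.Generator],
) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray]]:
    """Shared-source mixture activities for one coupling group.

    Returns (activities, common event train, private event trains).  The
    common and private trains are independent realizations of the same
    rate-λ transient process; each is standardized before mixing, so the
    expected pairwise correlation between any two members is exactly φ.
    The mixture is mapped back to the ΔF/F0 scale with the closed-form
    (Campbell) mean and SD of the rate-λ process.  Shared events appear
    with amplitude ≈ √φ·A and private events with ≈ √(1−φ)·A.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")
    n = int(round(recording_s / frame_interval_s))
    t = np.arange(n) * frame_interval_s
    lam = float(np.mean(member_rates)) if len(member_rates) else 0.0
    if member_rates and not np.allclose(member_rates, lam, rtol=1e-9, atol=1e-12):
        raise ValueError("coupled traces must share one event rate")
    if lam == 0.0:
        zeros = np.zeros(n)
        return (
            [zeros.copy() for _ in member_rates],
            np.empty(0),
            [np.empty(0) for _ in member_rates],
        )
    tau = decay_tau(params.amplitude_dff, params.duration_s, params.rise_s)
    i1, i2 = _template_integrals(params.rise_s, tau)
    mu_th = lam * params.amplitude_dff * i1
    sigma_th = params.amplitude_dff * math.sqrt(lam * i2)
    common = sample_event_train(lam, recording_s, common_rng)
    c_std = _standardize(
        activity_from_events(common, params.amplitude_dff, params.rise_s, tau, t)
    )
    activities = []
    privates = []
    for rng in member_rngs:
        priv = sample_event_train(lam, recording_s, rng)
        e_std = _standardize(
            activity_from_events(priv, params.amplitude_dff, params.rise_s, tau, t)
        )
        z = math.sqrt(phi) * c_std + math.sqrt(1.0 - phi) * e_std
        activities.append(mu_th + sigma_th * z)
        privates.append(priv)
    return activities, common, privates


def couple_traces(
    base_process: EventParams,
    phi: float,
    n: int,
    frame_interval_s: float,
    recording_s: float,
    rng: np.random.Generator,
) -> list[SimTrace]:
    """``n`` traces whose noiseless activities have pairwise correlation φ."""
    if n < 1:
        raise ValueError("n must be >= 1")
    # independent child streams so each trace's private randomness is
    # isolated; the first stream drives the common train
    children = rng.spawn(n + 1)
    acts, common, privates = _coupled_activities(
        base_process,
        phi,
        [base_process.rate_per_s] * n,
        frame_interval_s,
        recording_s,
        children[0],
        children[1:],
    )
    traces = []
    for a, priv, child in zip(acts, privates, children[1:]):
        sd = _noise_sd(base_process, a)
        F = base_process.baseline_f * (1.0 + a)
        if sd > 0:
            F = F + base_process.baseline_f * child.normal(0.0, sd, size=len(a))
        traces.append(
            SimTrace(F, a, common, priv, base_process, frame_interval_s)
        )
    return traces


# --------------------------------------------------------------------------
# conditions
# --------------------------------------------------------------------------

def _make_conditions(
    residual_fraction: float = 0.1,
    maturation_factor: float = 0.1,
    baseline_elevation: float = 3.0,
    ffa_phi: float = 0.08,
) -> dict[str, ConditionSpec]:
    hc = "hair_cell"
    sc = "supporting_cell"
    eff = "efferent_terminal"
    return {
        "control": ConditionSpec("control"),
        # lateral-line maturation: hair-cell and efferent activity wanes
        # by day 6 while supporting-cell activity persists
        "day6": ConditionSpec(
            "day6",
            rate_multipliers={
                (hc, "soma"): maturation_factor,
                (hc, "bundle"): maturation_factor,
                (hc, "presynapse"): maturation_factor,
                (eff, "terminal"): maturation_factor,
            },
        ),
        # P2ry1 antagonist: silences supporting cells
        "MRS2500": ConditionSpec(
            "MRS2500",
            rate_multipliers={(sc, "soma"): 0.0},
            metadata={"concentration": "1 uM"},
        ),
        # SERCA block: depletes ER stores -> supporting cells silenced,
        # cytosolic baseline strongly elevated
        "thapsigargin": ConditionSpec(
            "thapsigargin",
            rate_multipliers={(sc, "soma"): 0.0},
            baseline_multipliers={sc: baseline_elevation},
            metadata={"concentration": "250 nM"},
        ),
        # gap-junction block: supporting cells stay active but decouple
        "FFA": ConditionSpec(
            "FFA",
            phi_override={sc: ffa_phi},
            metadata={
                "concentration": "10 uM",
                "note": "drug table lists 25 uM; Results text uses 10 uM",
            },
        ),
        # CaV1.3 block/loss: abolishes presynaptic activity, bundles spared
        "isradipine": ConditionSpec(
            "isradipine",
            rate_multipliers={(hc, "presynapse"): 0.0},
            metadata={"concentration": "10 uM"},
        ),
        "cav1.3a": ConditionSpec(
            "cav1.3a", rate_multipliers={(hc, "presynapse"): 0.0}
        ),
        # tip-link disruption: MET-driven activity in bundle and
        # presynapse reduced to a residual fraction
        "BAPTA": ConditionSpec(
            "BAPTA",
            rate_multipliers={
                (hc, "bundle"): residual_fraction,
                (hc, "presynapse"): residual_fraction,
            },
            metadata={"concentration": "5 mM"},
        ),
        "pcdh15a": ConditionSpec(
            "pcdh15a",
            rate_multipliers={
                (hc, "bundle"): residual_fraction,
                (hc, "presynapse"): residual_fraction,
            },
        ),
        # efferent neurotransmission block: no effect on hair cells
        "aBtx_apamin": ConditionSpec(
            "aBtx_apamin",
            metadata={"concentration": "10 uM aBtx + 10 uM apamin"},
        ),
    }


CONDITIONS = _make_conditions()
CONDITION_NAMES = tuple(CONDITIONS)


def get_condition(name: str) -> ConditionSpec:
    try:
        return CONDITIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; valid conditions: "
            f"{', '.join(CONDITION_NAMES)}"
        ) from None


def apply_condition(
    model: NeuromastModel, condition: ConditionSpec | str
) -> NeuromastModel:
    """Pure parameter transform of a model under a condition switch."""
    if isinstance(condition, str):
        condition = get_condition(condition)
    cells = []
    for c in model.cells:
        comps = {}
        for comp, p in c.compartments.items():
            mult = condition.rate_multiplier(c.cell_type, comp)
            bmult = condition.baseline_multipliers.get(c.cell_type, 1.0)
            comps[comp] = EventParams(
                rate_per_s=p.rate_per_s * mult,
                amplitude_dff=p.amplitude_dff,
                duration_s=p.duration_s,
                rise_s=p.rise_s,
                baseline_f=p.baseline_f * bmult,
                noise_sd_dff=p.noise_sd_dff,
                noise_variance_ratio=p.noise_variance_ratio,
            )
        cells.append(
            CellSpec(c.cell_id, c.cell_type, c.position_um, comps, c.stage)
        )
    by_id = {c.cell_id: c for c in model.cells}
    coupling = []
    for a, b, phi in model.coupling:
        ta, tb = by_id[a[0]].cell_type, by_id[b[0]].cell_type
        if ta == tb and ta in condition.phi_override:
            phi = condition.phi_override[ta]
        coupling.append((a, b, phi))
    return NeuromastModel(
        neuromast_id=model.neuromast_id,
        cells=cells,
        coupling=coupling,
        recording_s=model.recording_s,
        frame_interval_s=model.frame_interval_s,
        seed=model.seed,
        condition=condition,
        extra=dict(model.extra),
    )


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

# Default event parameters.  Durations are the measured above-threshold
# event durations (hair cells 14.22 s, supporting cells 9.06 s); rates and
# amplitudes are package defaults chosen so ~5-11 sparse events occur in a
# 900 s recording, as in real traces.
def _hc_params() -> EventParams:
    return EventParams(rate_per_s=0.012, amplitude_dff=0.8, duration_s=14.22)


def _sc_params() -> EventParams:
    return EventParams(rate_per_s=0.005, amplitude_dff=0.5, duration_s=9.06)


def _eff_params(noise_variance_ratio: float = 0.05) -> EventParams:
    # efferent event duration is not reported; 10 s is a package default
    return EventParams(
        rate_per_s=0.01,
        amplitude_dff=0.6,
        duration_s=10.0,
        noise_variance_ratio=noise_variance_ratio,
    )


#: φ values for the documented coupling classes.
PHI_SC_SC = 0.50
PHI_HC_HC = 0.28
PHI_EFFERENT = 1.0
PHI_BUNDLE_PRESYNAPSE_DAY2 = 0.60
PHI_FFA = 0.08

_FIELD_CENTER_UM = (10.0, 10.0)  # (x, y) of the rosette center


def _ring_positions(
    n: int, radius_um: float, z_um: float, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Cells on a jittered ring — a rosette in top-down view."""
    cx, cy = _FIELD_CENTER_UM
    out = []
    for i in range(n):
        ang = 2.0 * math.pi * i / n + rng.normal(0.0, 0.03)
        r = radius_um * (1.0 + rng.normal(0.0, 0.04))
        out.append((cx + r * math.cos(ang), cy + r * math.sin(ang), z_um))
    return out


def _all_pairs(members: Sequence[Member], phi: float):
    return [
        (members[i], members[j], phi)
        for i in range(len(members))
        for j in range(i + 1, len(members))
    ]


def _geometry_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 97]))


def _preset_hair_cells(seed: int, n_cells: int, stage: str = "intermediate",
                       frame_interval_s: float = 3.0) -> NeuromastModel:
    g = _geometry_rng(seed)
    cells = []
    for i, pos in enumerate(_ring_positions(n_cells, 4.0, 6.0, g)):
        cells.append(
            CellSpec(
                f"hc{i + 1}",
                "hair_cell",
                pos,
                {
                    "soma": _hc_params(),
                    "bundle": _hc_params(),
                    "presynapse": _hc_params(),
                },
                stage=stage,
            )
        )
    soma = [(c.cell_id, "soma") for c in cells]
    return NeuromastModel(
        neuromast_id="nm1",
        cells=cells,
        coupling=_all_pairs(soma, PHI_HC_HC),
        recording_s=900.0,
        frame_interval_s=frame_interval_s,
        seed=seed,
    )


def _preset_supporting(seed: int, n_cells: int,
                       frame_interval_s: float = 3.0) -> NeuromastModel:
    g = _geometry_rng(seed)
    cells = [
        CellSpec(f"sc{i + 1}", "supporting_cell", pos, {"soma": _sc_params()})
        for i, pos in enumerate(_ring_positions(n_cells, 8.0, 6.0, g))
    ]
    soma = [(c.cell_id, "soma") for c in cells]
    return NeuromastModel(
        "nm1", cells, _all_pairs(soma, PHI_SC_SC), 900.0, frame_interval_s, seed
    )


def _preset_efferent(seed: int, n_cells: int,
                     frame_interval_s: float = 3.0) -> NeuromastModel:
    g = _geometry_rng(seed)
    cells = [
        CellSpec(f"eff{i + 1}", "efferent_terminal", pos,
                 {"terminal": _eff_params()})
        for i, pos in enumerate(_ring_positions(n_cells, 4.0, 8.0, g))
    ]
    term = [(c.cell_id, "terminal") for c in cells]
    return NeuromastModel(
        "nm1", cells, _all_pairs(term, PHI_EFFERENT), 900.0, frame_interval_s,
        seed,
    )


def _preset_two_color_hc_sc(seed: int, n_cells: Optional[int]) -> NeuromastModel:
    n_hc = 5
    n_sc = n_cells if n_cells else 10
    g = _geometry_rng(seed)
    cells = []
    for i, pos in enumerate(_ring_positions(n_hc, 4.0, 6.0, g)):
        cells.append(
            CellSpec(f"hc{i + 1}", "hair_cell", pos, {
                "soma": _hc_params(), "bundle": _hc_params(),
                "presynapse": _hc_params(),
            })
        )
    for i, pos in enumerate(_ring_positions(n_sc, 8.0, 6.0, g)):
        cells.append(
            CellSpec(f"sc{i + 1}", "supporting_cell", pos,
                     {"soma": _sc_params()})
        )
    hc = [(c.cell_id, "soma") for c in cells if c.cell_type == "hair_cell"]
    sc = [(c.cell_id, "soma") for c in cells if c.cell_type == "supporting_cell"]
    # hair cells and supporting cells are generated as independent
    # processes: the HC-SC shared-variance fraction is zero
    coupling = _all_pairs(hc, PHI_HC_HC) + _all_pairs(sc, PHI_SC_SC)
    return NeuromastModel("nm1", cells, coupling, 900.0, 5.0, seed)


def _preset_two_color_hc_eff(seed: int, n_cells: Optional[int]) -> NeuromastModel:
    n_pairs = n_cells if n_cells else 10
    g = _geometry_rng(seed)
    cells = []
    hc_pos = _ring_positions(n_pairs, 4.0, 6.0, g)
    for i, pos in enumerate(hc_pos):
        cells.append(
            CellSpec(f"hc{i + 1}", "hair_cell", pos, {
                "soma": _hc_params(), "bundle": _hc_params(),
                "presynapse": _hc_params(),
            })
        )
    for i, (x, y, z) in enumerate(hc_pos):
        # each terminal contacts its hair cell from below
        cells.append(
            CellSpec(f"eff{i + 1}", "efferent_terminal", (x, y, z + 2.0),
                     {"terminal": _eff_params()})
        )
    hc = [(f"hc{i + 1}", "soma") for i in range(n_pairs)]
    term = [(f"eff{i + 1}", "terminal") for i in range(n_pairs)]
    coupling = _all_pairs(hc, PHI_HC_HC) + _all_pairs(term, PHI_EFFERENT)
    return NeuromastModel("nm1", cells, coupling, 900.0, 5.0, seed)


def _preset_bundle_presynapse(seed: int, n_cells: int) -> NeuromastModel:
    model = _preset_hair_cells(seed, n_cells, stage="late")
    coupling = [
        ((c.cell_id, "bundle"), (c.cell_id, "presynapse"),
         PHI_BUNDLE_PRESYNAPSE_DAY2)
        for c in model.cells
    ]
    model.coupling = coupling
    return model


#: Wave-preset geometry/timing defaults (single supporting cell imaged in
#: cross section at 10 frames/s).
WAVE_DEFAULTS = dict(
    delay_s=0.3,           # programmed apex->base onset delay
    cell_height_um=12.0,
    cell_width_um=3.0,
    rate_per_s=0.02,       # faster than the volumetric preset so a short
    recording_s=120.0,     # recording reliably contains >= 1 event
    frame_interval_s=0.1,
    # single-plane imaging dwells ~10x longer per plane than volumetric
    # scanning, so the rendered movie collects ~20x the photons
    photon_scale=20.0,
)


def _preset_sc_wave(seed: int, n_cells: Optional[int]) -> NeuromastModel:
    w = dict(WAVE_DEFAULTS)
    p = _sc_params()
    params = EventParams(
        rate_per_s=w["rate_per_s"],
        amplitude_dff=p.amplitude_dff,
        duration_s=p.duration_s,
        noise_sd_dff=p.noise_sd_dff,
    )
    cell = CellSpec(
        "sc1",
        "supporting_cell",
        # centered in the narrow single-plane cross-section field
        (4.0, 12.0, 0.0),
        # positional sub-ROIs along the apex->base axis
        {"top": params, "middle": params, "bottom": params},
    )
    return NeuromastModel(
        "nm1", [cell], [], w["recording_s"], w["frame_interval_s"], seed,
        extra={"wave": w},
    )


_PRESET_BUILDERS: dict[str, Callable[[int, Optional[int]], NeuromastModel]] = {
    "hair_cell_day3": lambda s, n: _preset_hair_cells(s, n or 10),
    "hair_cell_day6": lambda s, n: apply_condition(
        _preset_hair_cells(s, n or 10), "day6"
    ),
    "supporting_day3": lambda s, n: _preset_supporting(s, n or 10),
    "supporting_day6": lambda s, n: apply_condition(
        _preset_supporting(s, n or 10), "day6"
    ),
    "efferent_day3": lambda s, n: _preset_efferent(s, n or 10),
    "two_color_hc_sc": _preset_two_color_hc_sc,
    "two_color_hc_eff": _preset_two_color_hc_eff,
    "bundle_presynapse_day2": lambda s, n: _preset_bundle_presynapse(s, n or 10),
    "sc_wave_singleplane": _preset_sc_wave,
}

PRESET_NAMES = tuple(_PRESET_BUILDERS)


def build_preset(
    name: str,
    seed: int,
    n_cells: Optional[int] = None,
    condition: Optional[ConditionSpec | str] = None,
) -> NeuromastModel:
    """Build a fully parameterized model from the preset catalog.

    ``name`` may carry a condition suffix, e.g. ``"supporting_day3+FFA"``.
    """
    if "+" in name:
        name, suffix = name.split("+", 1)
        if condition is not None:
            raise ValueError("give the condition either as suffix or keyword")
        condition = suffix
    if name not in _PRESET_BUILDERS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: "
            f"{', '.join(PRESET_NAMES)}"
        )
    model = _PRESET_BUILDERS[name](int(seed), n_cells)
    model.extra["preset"] = name
    if condition is not None:
        model = apply_condition(model, condition)
    return model


# --------------------------------------------------------------------------
# model-level trace generation
# --------------------------------------------------------------------------

@dataclass
class TraceBundle:
    """All simulated traces of one neuromast recording."""

    model: NeuromastModel
    traces: dict[Member, SimTrace]

    @property
    def frame_interval_s(self) -> float:
        return self.model.frame_interval_s

    @property
    def recording_s(self) -> float:
        return self.model.recording_s

    def members_of_type(
        self, cell_type: str, compartment: Optional[str] = None
    ) -> list[Member]:
        out = []
        for c in self.model.cells:
            if c.cell_type != cell_type:
                continue
            for comp in c.compartments:
                if compartment is None or comp == compartment:
                    out.append((c.cell_id, comp))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy raw-trace table (one row per member per frame)."""
        rows = []
        for (cell_id, comp), tr in self.traces.items():
            n = len(tr.F)
            rows.append(
                pd.DataFrame(
                    {
                        "neuromast_id": self.model.neuromast_id,
                        "cell_id": cell_id,
                        "compartment": comp,
                        "frame": np.arange(n),
                        "time_s": np.arange(n) * tr.frame_interval_s,
                        "F": tr.F,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _member_params(model: NeuromastModel, member: Member) -> EventParams:
    return model.cell(member[0]).compartments[member[1]]


def generate_traces(model: NeuromastModel) -> TraceBundle:
    """Render every compartment trace of a model, ground truth included.

    Randomness is organized as one independent child stream per coupling
    group (the shared train) plus one per member (private train, then
    noise), all spawned deterministically from ``model.seed``.  A
    condition that silences one compartment therefore leaves every other
    compartment's trace bit-identical at a matched seed.
    """
    if "wave" in model.extra:
        return _generate_wave_traces(model)
    members = model.members()
    groups = model.coupling_groups()
    ss = np.random.SeedSequence(int(model.seed) % 2**31)
    children = ss.spawn(len(groups) + len(members))
    group_rngs = [np.random.default_rng(c) for c in children[: len(groups)]]
    member_rngs = {
        m: np.random.default_rng(c)
        for m, c in zip(members, children[len(groups):])
    }
    n = model.n_frames
    t = np.arange(n) * model.frame_interval_s
    traces: dict[Member, SimTrace] = {}
    grouped: set[Member] = set()
    for g, grng in zip(groups, group_rngs):
        grouped.update(g.members)
        params = _member_params(model, g.members[0])
        rates = [_member_params(model, m).rate_per_s for m in g.members]
        acts, common, privates = _coupled_activities(
            params,
            g.phi,
            rates,
            model.frame_interval_s,
            model.recording_s,
            grng,
            [member_rngs[m] for m in g.members],
        )
        for m, a, priv in zip(g.members, acts, privates):
            p = _member_params(model, m)
            rng = member_rngs[m]
            sd = _noise_sd(p, a)
            F = p.baseline_f * (1.0 + a)
            if sd > 0:
                F = F + p.baseline_f * rng.normal(0.0, sd, size=n)
            traces[m] = SimTrace(F, a, common, priv, p, model.frame_interval_s)
    for m in members:
        if m in grouped:
            continue
        p = _member_params(model, m)
        rng = member_rngs[m]
        events = sample_event_train(p.rate_per_s, model.recording_s, rng)
        traces[m] = render_trace(
            events, p, model.frame_interval_s, model.recording_s, rng
        )
    return TraceBundle(model, traces)


def _wave_delays(model: NeuromastModel) -> dict[str, float]:
    d = model.extra["wave"]["delay_s"]
    return {"top": 0.0, "middle": d / 2.0, "bottom": d}


def _generate_wave_traces(model: NeuromastModel) -> TraceBundle:
    """Single-cell calcium wave: one train, position-dependent onset delay."""
    cell = model.cells[0]
    params = next(iter(cell.compartments.values()))
    ss = np.random.SeedSequence(int(model.seed) % 2**31)
    train_rng, *noise_rngs = (
        np.random.default_rng(c) for c in ss.spawn(1 + len(cell.compartments))
    )
    events = sample_event_train(params.rate_per_s, model.recording_s, train_rng)
    if len(events) == 0:
        # latency estimation needs at least one event; a deterministic
        # fallback event keeps short recordings usable
        events = np.array([model.recording_s / 3.0])
    tau = decay_tau(params.amplitude_dff, params.duration_s, params.rise_s)
    n = model.n_frames
    t = np.arange(n) * model.frame_interval_s
    traces: dict[Member, SimTrace] = {}
    for (comp, p), rng in zip(cell.compartments.items(), noise_rngs):
        delay = _wave_delays(model)[comp]
        a = activity_from_events(
            events, p.amplitude_dff, p.rise_s, tau, t - delay
        )
        sd = _noise_sd(p, a)
        F = p.baseline_f * (1.0 + a)
        if sd > 0:
            F = F + p.baseline_f * rng.normal(0.0, sd, size=n)
        traces[(cell.cell_id, comp)] = SimTrace(
            F, a, np.empty(0), events, p, model.frame_interval_s
        )
    return TraceBundle(model, traces)


# --------------------------------------------------------------------------
# ROI bookkeeping and movie rendering
# --------------------------------------------------------------------------

def default_rois(
    model: NeuromastModel,
    pixel_spacing_um: float = DEFAULT_VOXEL_SPACING_UM[1],
) -> list[Roi]:
    """Ground-truth ROIs at each compartment's blob center, in pixels."""
    if "wave" in model.extra:
        return _wave_rois(model, pixel_spacing_um)
    rois = []
    for c in model.cells:
        for comp in c.compartments:
            x, y, _z = c.position_um
            rois.append(
                Roi(
                    model.neuromast_id,
                    c.cell_id,
                    c.cell_type,
                    comp,
                    x / pixel_spacing_um,
                    y / pixel_spacing_um,
                    default_roi_diameter_um(c.cell_type, comp),
                )
            )
    return rois


def _wave_rois(model: NeuromastModel, pixel_spacing_um: float) -> list[Roi]:
    w = model.extra["wave"]
    cell = model.cells[0]
    cx, cy, _ = cell.position_um
    h = w["cell_height_um"]
    offsets = {"top": -h / 2.0, "middle": 0.0, "bottom": h / 2.0}
    return [
        Roi(
            model.neuromast_id,
            cell.cell_id,
            cell.cell_type,
            comp,
            cx / pixel_spacing_um,
            (cy + offsets[comp]) / pixel_spacing_um,
            3.0,  # supporting-cell soma ROI convention
        )
        for comp in cell.compartments
    ]


def render_movie(
    model: NeuromastModel,
    image_shape: Optional[tuple[int, int, int]] = None,
    voxel_spacing_um: tuple[float, float, float] = DEFAULT_VOXEL_SPACING_UM,
    drift_px_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0),
    rng: Optional[np.random.Generator] = None,
    include_noise: bool = True,
    background: float = 20.0,
    photon_scale: float = 1.0,
    read_noise_sd: float = 0.0,
):
    """Render a model as a T,Z,Y,X intensity movie.

    Each compartment becomes a 3D Gaussian blob (FWHM = its ROI diameter)
    whose brightness follows its rendered noiseless activity; Poisson shot
    noise (intensities are treated as photon counts, scaled by
    ``photon_scale``) and optional Gaussian read noise are added, and a
    rigid per-frame translation drift can be accumulated.

    Returns ``(VolumeSeries, metadata)`` where metadata records the
    ground-truth ROI centers and the injected cumulative drift.
    """
    from .imaging_io import VolumeSeries  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(int(model.seed) % 2**31 + 1)
    bundle = generate_traces(model)
    dz, dy, dx = voxel_spacing_um
    if "wave" in model.extra:
        return _render_wave_movie(
            model, bundle, image_shape, voxel_spacing_um, rng,
            include_noise, background, photon_scale, read_noise_sd,
        )
    if image_shape is None:
        image_shape = (12, 64, 64)
    nz, ny, nx = image_shape
    n = model.n_frames
    drift = np.asarray(drift_px_per_frame, dtype=float)
    cum_drift = np.arange(n)[:, None] * drift[None, :]  # (T, 3) in px

    blobs = []
    for c in model.cells:
        x, y, z = c.position_um
        cz, cy_, cx_ = z / dz, y / dy, x / dx
        if not (0 <= cz < nz and 0 <= cy_ < ny and 0 <= cx_ < nx):
            raise ValueError(
                f"cell {c.cell_id} at voxel ({cz:.1f}, {cy_:.1f}, {cx_:.1f}) "
                f"lies outside the field {image_shape}"
            )
        for comp in c.compartments:
            diam = default_roi_diameter_um(c.cell_type, comp)
            sigma_px = (diam / 2.355) / np.array([dz, dy, dx])
            tr = bundle.traces[(c.cell_id, comp)]
            blobs.append(((cz, cy_, cx_), sigma_px, tr))

    zax = np.arange(nz, dtype=float)
    yax = np.arange(ny, dtype=float)
    xax = np.arange(nx, dtype=float)
    movie = np.empty((n, nz, ny, nx), dtype=float)
    for ti in range(n):
        frame = np.full((nz, ny, nx), float(background))
        off = cum_drift[ti]
        for (cz, cy_, cx_), sig, tr in blobs:
            gz = np.exp(-0.5 * ((zax - (cz + off[0])) / sig[0]) ** 2)
            gy = np.exp(-0.5 * ((yax - (cy_ + off[1])) / sig[1]) ** 2)
            gx = np.exp(-0.5 * ((xax - (cx_ + off[2])) / sig[2]) ** 2)
            amp = tr.params.baseline_f * (1.0 + tr.activity[ti])
            frame += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        # photon_scale models exposure/collection efficiency: it scales
        # the expected photon count of signal and background alike
        movie[ti] = photon_scale * frame
    if include_noise:
        movie = rng.poisson(movie).astype(float)
        if read_noise_sd > 0:
            movie += rng.normal(0.0, read_noise_sd, size=movie.shape)
    series = VolumeSeries(
        data=movie,
        frame_interval_s=model.frame_interval_s,
        voxel_spacing_um=voxel_spacing_um,
        channel="GCaMP6s",
    )
    metadata = {
        "neuromast_id": model.neuromast_id,
        "roi_centers_px": {
            f"{cid}:{comp}": [
                model.cell(cid).position_um[0] / dx,
                model.cell(cid).position_um[1] / dy,
                model.cell(cid).position_um[2] / dz,
            ]
            for cid, comp in bundle.traces
        },
        "cum_drift_px": cum_drift.tolist(),
        "seed": model.seed,
    }
    return series, metadata


def _render_wave_movie(
    model: NeuromastModel,
    bundle: TraceBundle,
    image_shape,
    voxel_spacing_um,
    rng,
    include_noise,
    background,
    photon_scale,
    read_noise_sd,
):
    """Single-plane movie of an intracellular apex->base calcium wave.

    The cell is an elongated 2D Gaussian; the activity of each image row
    is delayed linearly from 0 at the top sub-ROI center to the full
    programmed delay at the bottom sub-ROI center.
    """
    from .imaging_io import VolumeSeries

    w = model.extra["wave"]
    if photon_scale == 1.0:
        photon_scale = w.get("photon_scale", 1.0)
    _dz, dy, dx = voxel_spacing_um
    if image_shape is None:
        image_shape = (1, 72, 24)
    _nz, ny, nx = image_shape
    cell = model.cells[0]
    params = next(iter(cell.compartments.values()))
    tr = bundle.traces[(cell.cell_id, "top")]
    events = tr.event_times
    tau = decay_tau(params.amplitude_dff, params.duration_s, params.rise_s)
    cx_um, cy_um, _ = cell.position_um
    cx_px, cy_px = cx_um / dx, cy_um / dy
    h_px = w["cell_height_um"] / dy
    y_top, y_bot = cy_px - h_px / 2.0, cy_px + h_px / 2.0
    sig_y = h_px / 2.355
    sig_x = (w["cell_width_um"] / dx) / 2.355
    n = model.n_frames
    t = np.arange(n) * model.frame_interval_s
    yax = np.arange(ny, dtype=float)
    xax = np.arange(nx, dtype=float)
    frac = np.clip((yax - y_top) / (y_bot - y_top), 0.0, 1.0)
    delays = frac * w["delay_s"]  # per-row onset delay
    # activity on the (frame, row) grid with the row's delay
    a = activity_from_events(
        events, params.amplitude_dff, params.rise_s, tau,
        t[:, None] - delays[None, :],
    )
    gy = np.exp(-0.5 * ((yax - cy_px) / sig_y) ** 2)
    gx = np.exp(-0.5 * ((xax - cx_px) / sig_x) ** 2)
    movie = photon_scale * (
        background
        + params.baseline_f * (1.0 + a)[:, :, None]
        * (gy[None, :, None] * gx[None, None, :])
    )
    movie = movie[:, None, :, :]  # insert singleton Z
    if include_noise:
        movie = rng.poisson(movie).astype(float)
        if read_noise_sd > 0:
            movie += rng.normal(0.0, read_noise_sd, size=movie.shape)
    series = VolumeSeries(
        data=movie,
        frame_interval_s=model.frame_interval_s,
        voxel_spacing_um=voxel_spacing_um,
        channel="GCaMP6s",
    )
    metadata = {
        "neuromast_id": model.neuromast_id,
        "roi_centers_px": {
            f"{cell.cell_id}:top": [cx_px, y_top],
            f"{cell.cell_id}:middle": [cx_px, cy_px],
            f"{cell.cell_id}:bottom": [cx_px, y_bot],
        },
        "programmed_delay_s": w["delay_s"],
        "cum_drift_px": np.zeros((n, 3)).tolist(),
        "seed": model.seed,
    }
    return series, metadata


# --------------------------------------------------------------------------
# fixture bundles
# --------------------------------------------------------------------------

def _phi_pairs_json(model: NeuromastModel) -> list[dict]:
    return [
        {"a": list(a), "b": list(b), "phi": phi}
        for a, b, phi in model.coupling
    ]


def write_fixture_bundle(
    model: NeuromastModel,
    out_dir: str | Path,
    mode: str = "traces",
    **movie_kwargs,
) -> dict[str, Path]:
    """Write a self-describing simulation bundle to ``out_dir``.

    Trace mode emits ``traces.csv``; movie mode emits ``movie.tif`` with a
    JSON metadata sidecar.  Both emit the ROI table, the ground truth
    (event times, φ pairs, condition) and a manifest with seed and
    version.  Re-running with the same seed reproduces the trace CSV
    byte for byte.
    """
    from . import __version__
    from .imaging_io import write_volume_series
    from .traces import write_rois

    if mode not in ("traces", "movie"):
        raise ValueError("mode must be 'traces' or 'movie'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    bundle = generate_traces(model)
    if mode == "traces":
        paths["traces"] = out / "traces.csv"
        bundle.to_frame().to_csv(
            paths["traces"], index=False, float_format="%.9g"
        )
        pixel_spacing = DEFAULT_VOXEL_SPACING_UM[1]
    else:
        series, meta = render_movie(model, **movie_kwargs)
        paths["movie"] = out / "movie.tif"
        write_volume_series(series, paths["movie"])
        paths["movie_metadata"] = out / "movie_ground_truth.json"
        paths["movie_metadata"].write_text(json.dumps(meta, indent=1))
        pixel_spacing = series.voxel_spacing_um[1]

    paths["rois"] = out / "rois.csv"
    write_rois(default_rois(model, pixel_spacing), paths["rois"])

    truth = {
        "neuromast_id": model.neuromast_id,
        "condition": model.condition.name if model.condition else "control",
        "seed": model.seed,
        "phi_pairs": _phi_pairs_json(model),
        "event_times_s": {
            f"{cid}:{comp}": tr.event_times.tolist()
            for (cid, comp), tr in bundle.traces.items()
        },
    }
    paths["ground_truth"] = out / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=1))

    manifest = {
        "package": "nmspont",
        "version": __version__,
        "seed": model.seed,
        "mode": mode,
        "preset": model.extra.get("preset"),
        "condition": model.condition.name if model.condition else "control",
        "n_cells": len(model.cells),
        "recording_s": model.recording_s,
        "frame_interval_s": model.frame_interval_s,
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths
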