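"""Dielectrophoretic force physics and the calibrated manipulation model.

A cell in a non-uniform AC field experiences the time-averaged DEP force

    F = 2 pi r^3 eps_m Re[K(w)] grad(E^2)

where ``r`` is the cell radius, ``eps_m`` the medium permittivity and
``K(w)`` the Clausius-Mossotti factor, the polarisability contrast
between the (single-shell) cell and the suspending medium.  Re[K] > 0
means attraction toward high field (positive DEP, here: toward the
illuminated light-pattern edge), Re[K] < 0 repulsion.  Live cells keep
an intact, poorly conducting membrane and polarise strongly (pDEP at
100 kHz in low-conductivity sucrose); dead cells have a permeabilised
membrane, their cytoplasm equilibrates with the medium, and they
experience nDEP - the sign inversion the sorting protocol exploits.

The counterpart is Stokes drag, ``F = 6 pi r eta v``: the net
manipulation force of a moving light pattern is inferred from the
maximum pattern speed that still carries a cell (its escape velocity),
and conversely the model predicts that maximum speed from a calibrated
light-edge field-gradient profile

    |grad E^2|(d) = A(w) V^2 exp(-d / lambda(w))

with per-bandwidth focusing amplitude A, decay length lambda and exact
voltage-squared scaling (Laplace linearity of the field).  The four
printed 8-V maximum velocities anchor the calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield, replace

import numpy as np
import pandas as pd

from .errors import CalibrationError, ValidationError

__all__ = [
    "MediumProps", "CellDielectric", "ODEPConfig", "LightPattern",
    "ForceModel", "complex_permittivity", "single_shell_effective_permittivity",
    "clausius_mossotti", "cm_spectrum", "grad_E2_map", "dep_force",
    "stokes_drag", "manipulation_force_from_velocity",
    "max_manipulation_velocity", "class_max_velocity",
    "calibrate_force_model", "DEFAULT_ANCHORS",
    "live_cancer_cell", "dead_cancer_cell", "live_leukocyte", "dead_leukocyte",
]

EPS0 = 8.8541878128e-12  # F/m

# reference radii (um) used in calibration: cancer cells (PC-3 line,
# diameter 23 +/- 2.1 um) and leukocytes (diameter ~10 um)
CANCER_RADIUS = 11.5
LEUKOCYTE_RADIUS = 5.0


@dataclass(frozen=True)
class MediumProps:
    """Suspending medium: 250 mM sucrose, conductivity 3.4 uS/cm."""

    conductivity: float = 3.4e-4      # S/m
    rel_permittivity: float = 78.0
    viscosity: float = 1.0e-3         # Pa s

    def __post_init__(self):
        if min(self.conductivity, self.rel_permittivity, self.viscosity) <= 0:
            raise ValidationError("medium properties must be positive")

    @property
    def permittivity(self) -> float:
        return self.rel_permittivity * EPS0


@dataclass(frozen=True)
class CellDielectric:
    """Single-shell cell: conductive cytoplasm sphere wrapped in a thin
    membrane described by surface capacitance/conductance.

    Default parameter sets (see :func:`live_cancer_cell` etc.) encode the
    live/dead contrast: dead cells carry a high membrane conductance and
    a cytoplasm equilibrated with the low-conductivity medium, which
    flips Re[K] negative at the 100 kHz operating point.
    """

    radius: float                      # um
    membrane_capacitance: float = 1.0e-2   # F/m^2
    membrane_conductance: float = 1.0e2    # S/m^2
    cytoplasm_conductivity: float = 0.3    # S/m
    cytoplasm_rel_permittivity: float = 60.0
    viability: str = "live"
    cell_type: str = "cancer"
    enforce_sign_constraint: bool = True

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError("cell radius must be positive")
        if self.viability not in ("live", "dead"):
            raise ValidationError("viability must be 'live' or 'dead'")
        if not self.enforce_sign_constraint:
            return
        # sign-constraint check at the default operating point
        medium = MediumProps()
        k = clausius_mossotti(self, medium, 1.0e5).real
        if self.viability == "live" and k <= 0:
            raise ValidationError(
                "live-cell dielectric parameters give Re[K] <= 0 at the "
                "100 kHz / 3.4 uS/cm operating point")
        if self.viability == "dead" and k >= 0:
            raise ValidationError(
                "dead-cell dielectric parameters give Re[K] >= 0 at the "
                "100 kHz / 3.4 uS/cm operating point")


def live_cancer_cell(radius: float = CANCER_RADIUS) -> CellDielectric:
    return CellDielectric(radius=radius, viability="live", cell_type="cancer")


def dead_cancer_cell(radius: float = CANCER_RADIUS) -> CellDielectric:
    return CellDielectric(radius=radius, viability="dead", cell_type="cancer",
                          membrane_conductance=1.0e5,
                          cytoplasm_conductivity=3.4e-4,
                          cytoplasm_rel_permittivity=50.0)


def live_leukocyte(radius: float = LEUKOCYTE_RADIUS) -> CellDielectric:
    return CellDielectric(radius=radius, viability="live",
                          cell_type="leukocyte")


def dead_leukocyte(radius: float = LEUKOCYTE_RADIUS) -> CellDielectric:
    return CellDielectric(radius=radius, viability="dead",
                          cell_type="leukocyte",
                          membrane_conductance=1.0e5,
                          cytoplasm_conductivity=3.4e-4,
                          cytoplasm_rel_permittivity=50.0)


@dataclass(frozen=True)
class ODEPConfig:
    """AC drive: 2-10 V at 100 kHz; above ``aggregation_limit`` volts the
    chip shows cell aggregation, flagged (not simulated)."""

    voltage: float = 8.0
    frequency: float = 1.0e5
    chamber_height: float = 100.0     # um
    aggregation_limit: float = 8.0

    def __post_init__(self):
        if self.voltage <= 0 or self.frequency <= 0:
            raise ValidationError("voltage and frequency must be positive")
        if self.voltage > self.aggregation_limit:
            warnings.warn(
                f"voltage {self.voltage} V exceeds the aggregation limit "
                f"{self.aggregation_limit} V: cell aggregation risk",
                stacklevel=2)

    @property
    def aggregation_risk(self) -> bool:
        return self.voltage > self.aggregation_limit


@dataclass(frozen=True)
class LightPattern:
    """A projected virtual-electrode image: sweeping bar or hollow circle.

    ``bandwidth`` is the bar width (150/200/250 um) or the circular
    annulus width (20/40/60 um, outer-inner = 2 x bandwidth around the
    fixed 40 um inner diameter).
    """

    kind: str = "bar"
    bandwidth: float = 150.0
    bar_length: float = 1000.0
    circle_inner_diameter: float = 40.0
    position: tuple[float, float] = (0.0, 0.0)
    speed: float = 0.0
    heading: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.kind not in ("bar", "hollow_circle"):
            raise ValidationError("pattern kind must be 'bar' or "
                                  "'hollow_circle'")
        if self.bandwidth <= 0:
            raise ValidationError("bandwidth must be positive")
        if self.speed < 0:
            raise ValidationError("pattern speed must be non-negative")

    @property
    def circle_outer_diameter(self) -> float:
        return self.circle_inner_diameter + 2.0 * self.bandwidth


# ---------------------------------------------------------------------------
# dielectric building blocks
# ---------------------------------------------------------------------------

def complex_permittivity(conductivity: float, rel_permittivity: float,
                         frequency: float) -> complex:
    """eps* = eps - j sigma / omega with omega = 2 pi f (SI units)."""
    if frequency <= 0:
        raise ValidationError("frequency must be positive")
    omega = 2.0 * np.pi * frequency
    return rel_permittivity * EPS0 - 1j * conductivity / omega


def single_shell_effective_permittivity(cell: CellDielectric,
                                        frequency: float) -> complex:
    """Effective eps* of the shelled sphere (thin-membrane reduction).

    With the membrane as a surface admittance Y_m = G_m + j w C_m, its
    complex specific capacitance is c* = C_m - j G_m / w and

        eps*_p = r c* eps*_i / (r c* + eps*_i)

    which tends to the bare cytoplasm value as c* -> inf (transparent
    shell) and to r c* when the membrane dominates (low frequency,
    intact membrane).
    """
    omega = 2.0 * np.pi * frequency
    eps_i = complex_permittivity(cell.cytoplasm_conductivity,
                                 cell.cytoplasm_rel_permittivity, frequency)
    c_mem = cell.membrane_capacitance - 1j * cell.membrane_conductance / omega
    r_m = cell.radius * 1e-6
    return r_m * c_mem * eps_i / (r_m * c_mem + eps_i)


def clausius_mossotti(cell: CellDielectric, medium: MediumProps,
                      frequency: float) -> complex:
    """K = (eps*_p - eps*_m) / (eps*_p + 2 eps*_m); Re[K] in [-0.5, 1]."""
    eps_p = single_shell_effective_permittivity(cell, frequency)
    eps_m = complex_permittivity(medium.conductivity, medium.rel_permittivity,
                                 frequency)
    denom = eps_p + 2.0 * eps_m
    assert abs(denom) > 0, "degenerate CM denominator (unphysical input)"
    return (eps_p - eps_m) / denom


def cm_spectrum(cell: CellDielectric, medium: MediumProps,
                frequencies: np.ndarray) -> pd.DataFrame:
    """Tidy (frequency_Hz, ReK, ImK) table over a frequency sweep."""
    ks = [clausius_mossotti(cell, medium, f) for f in np.asarray(frequencies)]
    return pd.DataFrame({"frequency_Hz": np.asarray(frequencies, float),
                         "ReK": [k.real for k in ks],
                         "ImK": [k.imag for k in ks]})


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def dep_force(radius: float, medium: MediumProps, ReK: float,
              gradE2: float) -> float:
    """DEP force in newtons: 2 pi r^3 eps_m Re[K] grad(E^2).

    ``radius`` in um, ``gradE2`` in V^2/m^3.  Positive = attraction
    toward the illuminated edge.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    r = radius * 1e-6
    return 2.0 * np.pi * r ** 3 * medium.permittivity * ReK * gradE2


def stokes_drag(radius: float, viscosity: float, velocity: float) -> float:
    """Stokes drag in newtons: 6 pi r eta v (radius um, velocity um/s)."""
    if radius <= 0 or viscosity <= 0:
        raise ValidationError("radius and viscosity must be positive")
    return 6.0 * np.pi * (radius * 1e-6) * viscosity * (velocity * 1e-6)


def manipulation_force_from_velocity(cell: CellDielectric,
                                     medium: MediumProps,
                                     v_max: float) -> float:
    """Net manipulation force (N) inferred from a maximum manipulation
    velocity via Stokes drag.  This is the *net* force (ODEP minus
    surface friction), the quantity the moving-light-image measurement
    actually probes."""
    if v_max < 0:
        raise ValidationError("v_max must be non-negative")
    return stokes_drag(cell.radius, medium.viscosity, v_max)


# ---------------------------------------------------------------------------
# calibrated force model
# ---------------------------------------------------------------------------

# fixed per-bandwidth attenuation ladder of the focusing amplitude,
# relative to the calibrated reference bandwidth of each pattern kind.
# Encodes the observed orderings: narrower bars focus the field better
# (150 > 200 > 250 um), and for the hollow circle the 40 um annulus is
# optimal while 20 um (comparable to the cell diameter) destabilises
# the trap and is attenuated hardest.
BAR_ATTENUATION = {150.0: 1.0, 200.0: 0.85, 250.0: 0.70}
CIRCLE_ATTENUATION = {40.0: 1.0, 60.0: 0.80, 20.0: 0.45}
REFERENCE_BANDWIDTH = {"bar": 150.0, "hollow_circle": 40.0}
UNSTABLE_CIRCLE_BANDWIDTH = 20.0

# printed 8-V anchor velocities (um/s): the Fig. 4 operating points
DEFAULT_ANCHORS = pd.DataFrame([
    ("leukocyte", "live", "bar", 150.0, 8.0, 250.49),
    ("leukocyte", "dead", "bar", 150.0, 8.0, 115.57),
    ("cancer", "live", "hollow_circle", 40.0, 8.0, 290.01),
    ("cancer", "dead", "hollow_circle", 40.0, 8.0, 82.84),
], columns=["cell_class", "viability", "pattern_kind", "bandwidth_um",
            "voltage_V", "v_max_um_s"])

REFERENCE_RADII = {"cancer": CANCER_RADIUS, "leukocyte": LEUKOCYTE_RADIUS}


@dataclass(frozen=True)
class ForceModel:
    """Calibrated light-edge field model + per-class polarisability scales.

    ``amplitude[(kind, bandwidth)]`` is A(w) in V^2 m^-3 per V^2;
    ``decay_length[(kind, bandwidth)]`` is lambda(w) in um;
    ``class_scale[(cell_class, viability)]`` is the effective |Re[K]|
    (sign carried separately by the cell's own CM factor) absorbing the
    per-class force-vs-friction balance the anchors embody.
    ``friction_absorbed`` records that the model predicts the *net*
    manipulation force.
    """

    amplitude: dict
    decay_length: dict
    class_scale: dict
    medium: MediumProps
    reference_radii: dict
    friction_absorbed: bool = True
    calibration_report: pd.DataFrame | None = dfield(default=None, repr=False)
    allow_interpolation: bool = False

    def focusing_amplitude(self, pattern: LightPattern) -> float:
        key = (pattern.kind, pattern.bandwidth)
        if key in self.amplitude:
            return self.amplitude[key]
        if self.allow_interpolation:
            table = {bw: a for (k, bw), a in self.amplitude.items()
                     if k == pattern.kind}
            bws = np.array(sorted(table))
            return float(np.interp(pattern.bandwidth, bws,
                                   [table[b] for b in bws]))
        raise ValidationError(
            f"no calibrated amplitude for {pattern.kind} bandwidth "
            f"{pattern.bandwidth} um (interpolation disabled)")

    def unstable(self, pattern: LightPattern) -> bool:
        """True for the 20 um circle annulus: bandwidth comparable to the
        cell size makes the trap unstable."""
        return (pattern.kind == "hollow_circle"
                and pattern.bandwidth <= UNSTABLE_CIRCLE_BANDWIDTH)


def grad_E2_map(pattern: LightPattern, config: ODEPConfig,
                model: ForceModel, distances: np.ndarray) -> np.ndarray:
    """|grad E^2| (V^2/m^3) at distances (um) from the illuminated edge:
    A(w) V^2 exp(-d/lambda(w)), peaked at the edge, exact in V^2."""
    A = model.focusing_amplitude(pattern)
    lam = model.decay_length.get((pattern.kind, pattern.bandwidth),
                                 pattern.bandwidth / 2.0)
    d = np.asarray(distances, float)
    return A * config.voltage ** 2 * np.exp(-np.abs(d) / lam)


def class_max_velocity(cell_type: str, viability: str, radius: float,
                       pattern: LightPattern, config: ODEPConfig,
                       model: ForceModel,
                       use_cell_radius: bool = False) -> float:
    """Maximum pattern speed (um/s) that still carries a cell of the
    given class: peak |DEP force| balanced against Stokes drag,

        v_max = r^2 eps_m k_cv A(w) V^2 / (3 eta).

    By default the class's calibration reference radius is used (the
    printed anchors were measured on cell populations, so the class
    anchor already carries the population's size); pass
    ``use_cell_radius=True`` to scale with the individual cell's r^2.
    """
    if model is None:
        raise ValidationError("force model required (run calibration first)")
    key = (cell_type, viability)
    if key not in model.class_scale:
        raise ValidationError(f"force model has no class scale for {key}")
    r_um = radius if use_cell_radius else model.reference_radii[cell_type]
    r = r_um * 1e-6
    A = model.focusing_amplitude(pattern)
    k = model.class_scale[key]
    eta = model.medium.viscosity
    v = r ** 2 * model.medium.permittivity * k * A * config.voltage ** 2 \
        / (3.0 * eta)
    return v * 1e6  # m/s -> um/s


def max_manipulation_velocity(cell: CellDielectric, pattern: LightPattern,
                              config: ODEPConfig, model: ForceModel,
                              use_cell_radius: bool = False) -> float:
    """Maximum speed (um/s) of a moving light pattern that still carries
    ``cell``; see :func:`class_max_velocity`."""
    return class_max_velocity(cell.cell_type, cell.viability, cell.radius,
                              pattern, config, model,
                              use_cell_radius=use_cell_radius)


def calibrate_force_model(config: ODEPConfig | None = None,
                          medium: MediumProps | None = None,
                          anchors: pd.DataFrame | None = None,
                          cells: dict | None = None) -> ForceModel:
    """Fit the force model to the printed 8-V maximum velocities.

    The per-bandwidth amplitudes follow the fixed attenuation ladder
    (encoding the Fig. 4 orderings); the reference amplitude is set from
    the physical DEP scale of the live-cancer anchor, and the four
    anchors are then matched exactly through the per-class effective
    polarisability scales.  Raises :class:`CalibrationError` if any
    anchor is reproduced worse than 5% or an ordering constraint fails.
    """
    config = config or ODEPConfig()
    medium = medium or MediumProps()
    anchors = DEFAULT_ANCHORS if anchors is None else anchors
    cells = cells or {
        ("cancer", "live"): live_cancer_cell(),
        ("cancer", "dead"): dead_cancer_cell(),
        ("leukocyte", "live"): live_leukocyte(),
        ("leukocyte", "dead"): dead_leukocyte(),
    }

    # physical reference amplitude: the live-cancer anchor force via
    # Stokes' law, inverted through the DEP formula at its own Re[K]
    ref = anchors[(anchors.cell_class == "cancer")
                  & (anchors.viability == "live")]
    if len(ref) == 0:
        raise CalibrationError("anchors must include a live cancer row")
    ref = ref.iloc[0]
    cell_ref = cells[("cancer", "live")]
    F_ref = stokes_drag(cell_ref.radius, medium.viscosity, ref.v_max_um_s)
    k_ref = clausius_mossotti(cell_ref, medium, config.frequency).real
    r_ref = cell_ref.radius * 1e-6
    A_ref = F_ref / (2.0 * np.pi * r_ref ** 3 * medium.permittivity
                     * abs(k_ref) * ref.voltage_V ** 2)

    amplitude = {}
    decay = {}
    for bw, att in BAR_ATTENUATION.items():
        amplitude[("bar", bw)] = A_ref * att
        decay[("bar", bw)] = bw / 2.0
    for bw, att in CIRCLE_ATTENUATION.items():
        amplitude[("hollow_circle", bw)] = A_ref * att
        decay[("hollow_circle", bw)] = bw / 2.0

    # per-class scales matching each anchor exactly at its own pattern
    class_scale = {}
    rows = []
    for _, a in anchors.iterrows():
        key = (a.cell_class, a.viability)
        A_w = amplitude[(a.pattern_kind, a.bandwidth_um)]
        r = REFERENCE_RADII[a.cell_class] * 1e-6
        v_target = a.v_max_um_s * 1e-6
        class_scale[key] = 3.0 * medium.viscosity * v_target / (
            r ** 2 * medium.permittivity * A_w * a.voltage_V ** 2)
        rows.append(dict(cell_class=a.cell_class, viability=a.viability,
                         anchor_um_s=a.v_max_um_s))

    model = ForceModel(amplitude=amplitude, decay_length=decay,
                       class_scale=class_scale, medium=medium,
                       reference_radii=dict(REFERENCE_RADII))

    # verify anchors and orderings
    residuals = []
    for row, (_, a) in zip(rows, anchors.iterrows()):
        cell = cells[(a.cell_class, a.viability)]
        pat = LightPattern(kind=a.pattern_kind, bandwidth=a.bandwidth_um)
        cfg = replace(config, voltage=a.voltage_V)
        v = max_manipulation_velocity(cell, pat, cfg, model)
        rel = abs(v - a.v_max_um_s) / a.v_max_um_s
        row["model_um_s"] = v
        row["rel_residual"] = rel
        residuals.append(rel)
    report = pd.DataFrame(rows)
    if max(residuals) > 0.05:
        raise CalibrationError("anchor residual exceeds 5%",
                               residuals=report)
    bar_a = [amplitude[("bar", b)] for b in (150.0, 200.0, 250.0)]
    circ_a = [amplitude[("hollow_circle", b)] for b in (40.0, 60.0, 20.0)]
    if not (bar_a[0] > bar_a[1] > bar_a[2]
            and circ_a[0] > circ_a[1] > circ_a[2]):
        raise CalibrationError("bandwidth ordering constraints violated",
                               residuals=report)
    return ForceModel(amplitude=amplitude, decay_length=decay,
                      class_scale=class_scale, medium=medium,
                      reference_radii=dict(REFERENCE_RADII),
                      calibration_report=report)
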