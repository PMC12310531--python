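"""Parameter containers and shipped default configurations.

The mechanistic skeleton is a two-compartment (nucleus / cytoplasm) cyclin--CDK
oscillator: total cyclin--CDK concentration ``C`` accumulates in the nucleus by
synthesis, is exported to the cytoplasm at mitotic onset, and is degraded at
mitotic exit.  The active (Y15-dephosphorylated) fraction ``A`` of each
compartment's pool is governed by a Wee1-like inactivating rate ``kw(A)`` and a
Cdc25-like activating rate ``k25(A)``, both Hill-regulated by CDK activity
itself, which produces the bistable, switch-like activation of the nucleus and
the weakly switched, low-threshold cytoplasm.

All rates are in min^-1, concentrations in arbitrary units (AU), lengths in
micrometres.  The shipped defaults (``default_wt`` / ``default_af`` /
``default_hpm``) were calibrated by simulation (scripts/calibrate.py) so the
emergent timing statistics of the full analysis pipeline match published
single-cell measurements in fission yeast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import yaml

__all__ = [
    "SwitchParams",
    "OscillatorParams",
    "SensorParams",
    "Protocol",
    "ImagingConfig",
    "default_wt",
    "default_af",
    "default_hpm",
    "nuccdk",
    "cytcdk",
    "cytcdk_v2",
    "default_sensors",
    "config_to_yaml",
    "config_from_yaml",
]

MODES = ("WT", "AF", "HPM")


@dataclass
class SwitchParams:
    """Y15-switch rates for one compartment.

    ``kw(A) = kw_lo + (kw_hi - kw_lo) * K_w^h / (K_w^h + A^h)`` (Wee1-like,
    high at low activity) and
    ``k25(A) = k25_lo + (k25_hi - k25_lo) * A^h / (K_25^h + A^h)`` (Cdc25-like,
    low at low activity).
    """

    kw_lo: float
    kw_hi: float
    k25_lo: float
    k25_hi: float
    K_w: float
    K_25: float
    h: float = 4.0

    def validate(self) -> None:
        for name in ("kw_lo", "kw_hi", "k25_lo", "k25_hi", "K_w", "K_25"):
            if getattr(self, name) < 0:
                raise ValueError(f"SwitchParams.{name} must be >= 0")
        if self.kw_hi < self.kw_lo:
            raise ValueError("kw_hi must be >= kw_lo")
        if self.k25_hi < self.k25_lo:
            raise ValueError("k25_hi must be >= k25_lo")
        if self.h < 1:
            raise ValueError("Hill coefficient h must be >= 1")

    def kw(self, a: float) -> float:
        ah = a**self.h if a > 0 else 0.0
        kh = self.K_w**self.h
        return self.kw_lo + (self.kw_hi - self.kw_lo) * kh / (kh + ah)

    def k25(self, a: float) -> float:
        ah = a**self.h if a > 0 else 0.0
        kh = self.K_25**self.h
        return self.k25_lo + (self.k25_hi - self.k25_lo) * ah / (kh + ah)


@dataclass
class OscillatorParams:
    """Two-compartment oscillator parameters.

    ``theta_act`` is the nuclear activation threshold on effective (inhibitor-
    scaled) activity; crossing it starts the export clock (lag ``tau_exp``);
    export then exchanges cyclin--CDK toward the partition ratio ``rho_exp``.
    ``theta_act_c`` is the analogous, much lower, cytoplasmic activation
    threshold.  Crossing ``theta_apc`` with the cytoplasmic activity starts the
    degradation clock (lag ``tau_apc``).  ``mode`` selects wild type (``WT``),
    the feedback-abolished Y15 mutant (``AF``, activity identical to total
    cyclin--CDK) or the hydrophobic-patch cyclin mutant (``HPM``, nuclear
    export disabled).
    """

    k_syn: float = 0.1
    nuclear: SwitchParams = field(
        default_factory=lambda: SwitchParams(
            kw_lo=0.02, kw_hi=0.9, k25_lo=0.04, k25_hi=0.6, K_w=1.3, K_25=1.3, h=4.0
        )
    )
    cytoplasmic: SwitchParams = field(
        default_factory=lambda: SwitchParams(
            kw_lo=0.01, kw_hi=0.25, k25_lo=0.05, k25_hi=0.5, K_w=0.3, K_25=0.3, h=4.0
        )
    )
    k_exp_max: float = 0.55
    tau_exp: float = 3.5
    theta_act: float = 8.5
    theta_act_c: float = 0.1
    theta_apc: float = 0.6
    tau_apc: float = 16.0
    k_deg_max: float = 0.35
    phi_n: float = 0.15
    rho_exp: float = 3.0
    mode: str = "WT"
    r_len: float = 0.06
    L0: float = 7.0
    C_n0: float = 2.0
    k_wash: float = 0.075

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in (
            "k_syn",
            "k_exp_max",
            "tau_exp",
            "theta_act",
            "theta_act_c",
            "theta_apc",
            "tau_apc",
            "k_deg_max",
            "rho_exp",
            "r_len",
            "L0",
            "C_n0",
            "k_wash",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"OscillatorParams.{name} must be >= 0")
        if not 0 < self.phi_n < 1:
            raise ValueError("phi_n must lie strictly between 0 and 1")
        self.nuclear.validate()
        self.cytoplasmic.validate()

    @property
    def export_coupling(self) -> float:
        """Volume-fraction weight converting a nuclear concentration flux into
        a cytoplasmic one, so export conserves molecule number."""
        return self.phi_n / (1.0 - self.phi_n)


SENSOR_KINDS = ("NucCDK", "CytCDK", "CytCDKv2")


@dataclass
class SensorParams:
    """Translocation-sensor kinetics.

    ``p`` is the phosphorylated fraction, driven by the effective activity of
    the host compartment; ``f`` is the nuclear localization fraction relaxing
    at rate ``k_loc`` towards a target linear in ``p`` -- decreasing for
    NucCDK (nuclear at rest, exported when phosphorylated) and increasing for
    CytCDK/CytCDKv2 (cytoplasmic at rest, imported when phosphorylated).

    ``tau_off`` is a release latency (min): the drive the sensor responds to
    is the running maximum of the effective host activity over the past
    ``tau_off`` minutes, so rising activity is followed immediately while
    falling activity is seen only after the latency -- a minimal model of
    slow release of the phosphorylated sensor from its high-activity
    conformation/location, which produces the observed lag between acute CDK
    inhibition and the change in CytCDK readout without delaying the mitotic
    rise.
    """

    kind: str
    k_on: float
    k_off: float
    k_loc: float
    f_min: float
    f_max: float
    host: str  # "nucleus" or "cytoplasm"
    tau_off: float = 0.0

    def validate(self) -> None:
        if self.kind not in SENSOR_KINDS:
            raise ValueError(f"kind must be one of {SENSOR_KINDS}")
        if self.host not in ("nucleus", "cytoplasm"):
            raise ValueError("host must be 'nucleus' or 'cytoplasm'")
        for name in ("k_on", "k_off", "k_loc", "tau_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"SensorParams.{name} must be >= 0")
        if not 0 <= self.f_min < self.f_max <= 1:
            raise ValueError("require 0 <= f_min < f_max <= 1")

    def f_target(self, p: float) -> float:
        if self.kind == "NucCDK":
            return self.f_max - (self.f_max - self.f_min) * p
        return self.f_min + (self.f_max - self.f_min) * p

    def resting_f(self) -> float:
        return self.f_target(0.0)


def nuccdk() -> SensorParams:
    return SensorParams(
        kind="NucCDK", k_on=0.22, k_off=0.35, k_loc=0.8, f_min=0.15, f_max=0.95,
        host="nucleus",
    )


def cytcdk() -> SensorParams:
    return SensorParams(
        kind="CytCDK", k_on=0.6, k_off=2.0, k_loc=2.2, f_min=0.08, f_max=0.85,
        host="cytoplasm", tau_off=3.2,
    )


def cytcdk_v2() -> SensorParams:
    # same construct as CytCDK but with a serine acceptor site: higher
    # k_on/k_off ratio, i.e. sensitivity comparable to NucCDK
    return SensorParams(
        kind="CytCDKv2", k_on=1.1, k_off=2.0, k_loc=2.2, f_min=0.08, f_max=0.85,
        host="cytoplasm", tau_off=3.2,
    )


def default_sensors() -> list[SensorParams]:
    return [nuccdk(), cytcdk()]


@dataclass
class Protocol:
    """Inhibitor schedule ``iota(t)`` in [0, 1] (fraction of uninhibited
    catalytic activity).

    ``schedule`` is a list of ``(time, target)`` pairs, piecewise constant in
    target.  Downward transitions (drug addition) are instantaneous; upward
    transitions (drug washout at release) relax first order with rate
    ``k_wash``.  ``reset_after`` optionally resets the cell to its G1-like
    initial state that many minutes after degradation onset (free-running
    division).
    """

    schedule: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 1.0)])
    k_wash: float = 0.075
    reset_after: float | None = None

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValueError("schedule must contain at least one (time, target) pair")
        times = [t for t, _ in self.schedule]
        if sorted(times) != times:
            raise ValueError("schedule times must be non-decreasing")
        for _, u in self.schedule:
            if not 0.0 <= u <= 1.0:
                raise ValueError("iota targets must lie in [0, 1]")
        # value actually attained at the start of each segment
        self._starts: list[float] = []
        v = self.schedule[0][1]
        for i, (t_i, u_i) in enumerate(self.schedule):
            if i == 0:
                self._starts.append(u_i)
                v = u_i
                continue
            t_prev, u_prev = self.schedule[i - 1]
            v_prev = self._starts[i - 1]
            if u_prev <= v_prev:
                v = u_prev
            else:
                v = u_prev - (u_prev - v_prev) * math.exp(-self.k_wash * (t_i - t_prev))
            self._starts.append(v)

    def iota(self, t: float) -> float:
        """Inhibitor-scaled activity fraction at time ``t``."""
        idx = 0
        for i, (t_i, _) in enumerate(self.schedule):
            if t >= t_i:
                idx = i
            else:
                break
        t_i, u_i = self.schedule[idx]
        v_i = self._starts[idx]
        if u_i <= v_i:
            return u_i
        return u_i - (u_i - v_i) * math.exp(-self.k_wash * (t - t_i))


def free_running() -> Protocol:
    return Protocol(schedule=[(0.0, 1.0)])


def block_release(t_release: float, iota_hold: float = 0.05,
                  k_wash: float = 0.075) -> Protocol:
    """Hold CDK activity at ``iota_hold`` (G2 block), release at
    ``t_release`` with first-order inhibitor washout."""
    return Protocol(schedule=[(0.0, iota_hold), (t_release, 1.0)], k_wash=k_wash)


def acute_inhibition(t_inhibit: float) -> Protocol:
    """Run uninhibited, then add saturating inhibitor at ``t_inhibit``."""
    return Protocol(schedule=[(0.0, 1.0), (t_inhibit, 0.0)])


@dataclass
class ImagingConfig:
    """Synthetic timelapse rendering parameters.

    Pixel size defaults to 130 nm (2x2-binned sCMOS at 100x); the nuclear disk
    is sized so nuclear area is ~15% of cell area, matching the convention
    that justifies the top-15%-of-pixels nuclear intensity estimator.
    """

    dt_img: float = 5.0
    pixel_size_nm: float = 130.0
    cell_width_um: float = 3.5
    nuclear_area_fraction: float = 0.15
    frame_shape: tuple[int, int] = (48, 160)
    photon_scale: float = 100.0
    read_noise_sd: float = 2.0
    background: float = 100.0
    shot_noise: bool = True
    bit_depth: int = 16

    def validate(self) -> None:
        if self.dt_img <= 0:
            raise ValueError("dt_img must be positive")
        if not 0 < self.nuclear_area_fraction < 1:
            raise ValueError("nuclear_area_fraction must lie in (0, 1)")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")


def default_wt() -> OscillatorParams:
    return OscillatorParams(mode="WT")


def default_af() -> OscillatorParams:
    """Feedback-abolished (T14A/Y15F-like) configuration: the active fraction
    is identical to the total pool; Y15-switch rates are ignored."""
    return OscillatorParams(mode="AF")


def default_hpm() -> OscillatorParams:
    """Hydrophobic-patch cyclin mutant: no SPB localization, hence no nuclear
    export; the cytoplasm never receives cyclin--CDK."""
    return OscillatorParams(mode="HPM")


# ---------------------------------------------------------------------------
# YAML round-trip


def config_to_yaml(params: OscillatorParams, sensors: list[SensorParams] | None = None,
                   imaging: ImagingConfig | None = None) -> str:
    doc: dict = {"oscillator": asdict(params)}
    if sensors is not None:
        doc["sensors"] = [asdict(s) for s in sensors]
    if imaging is not None:
        d = asdict(imaging)
        d["frame_shape"] = list(imaging.frame_shape)
        doc["imaging"] = d
    return yaml.safe_dump(doc, sort_keys=False)


def config_from_yaml(text: str) -> dict:
    doc = yaml.safe_load(text)
    out: dict = {}
    if "oscillator" in doc:
        d = dict(doc["oscillator"])
        d["nuclear"] = SwitchParams(**d["nuclear"])
        d["cytoplasmic"] = SwitchParams(**d["cytoplasmic"])
        params = OscillatorParams(**d)
        params.validate()
        out["oscillator"] = params
    if "sensors" in doc:
        sensors = [SensorParams(**s) for s in doc["sensors"]]
        for s in sensors:
            s.validate()
        out["sensors"] = sensors
    if "imaging" in doc:
        d = dict(doc["imaging"])
        d["frame_shape"] = tuple(d["frame_shape"])
        cfg = ImagingConfig(**d)
        cfg.validate()
        out["imaging"] = cfg
    return out
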