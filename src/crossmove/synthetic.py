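"""Synthetic movement population with shared cross-domain individuality.

Emulates a cohort of athletically active adults, each of whom walks and
runs on a treadmill (per-foot vertical ground reaction force, 100 Hz,
pressure-insole style) and handwrites a sentence beginning with a
capital W (vertical pen pressure, 200 Hz, 12-bit device units).

The scientific premise being emulated is that a person's individuality
is a *single* latent factor expressed in every movement: each subject
carries a latent vector ``theta`` (standard normal, dimension 4), and
each movement domain owns a linear read-out ``A @ theta + b`` onto that
domain's waveform parameters (peak amplitudes, timings, stroke heights,
...).  Because the three domains read the same ``theta``, identity is
recoverable within each domain and — crucially — transferable across
domains, which is exactly what the translation model is asked to learn.

Waveforms:

* walking stance — the classic double-peaked vertical GRF: loading and
  terminal-stance peaks of ~1.0-1.2 body weight at ~25% and ~75% of
  stance with a mid-stance valley;
* running stance — an early impact peak (~10% of stance, ~1.4-1.8 BW)
  followed by a single larger active peak (~45%, ~2.2-2.6 BW), with a
  shorter stance and an aerial phase;
* handwriting — four pressure humps (the W strokes) on a positive
  pen-down baseline, optionally connected through a pressure valley to
  a smaller 'e' hump.

All curves are built from smooth shape-preserving interpolants or
Gaussian humps; within-subject variation enters as parameter noise
scaled relative to the between-subject spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "DOMAINS",
    "SPEED_FACTORS",
    "WRITING_INSTRUCTIONS",
    "GRAVITY",
    "SubjectLatent",
    "DomainMap",
    "RawForceRecording",
    "RawPenRecording",
    "InvalidPopulationError",
    "make_population",
    "make_domain_maps",
    "simulate_walking_recording",
    "simulate_running_recording",
    "simulate_writing_trial",
    "save_recording",
    "load_recording",
]

DOMAINS = ("walking", "running", "writing")

#: treadmill speed conditions: fraction of preferred walking/running speed
SPEED_FACTORS = {"slow": 0.85, "normal": 1.0, "fast": 1.15}

WRITING_INSTRUCTIONS = (
    "normal", "bigger", "smaller", "faster", "slower", "more beautiful",
)

GRAVITY = 9.81  # m/s^2

FORCE_HZ = 100
PEN_HZ = 200
CONTACT_THRESHOLD_N = 50.0
PEN_MAX_LEVEL = 4095

LATENT_DIM = 4


class InvalidPopulationError(ValueError):
    """Raised when a population cannot support classification (< 2 subjects)."""


@dataclass(frozen=True)
class SubjectLatent:
    """One synthetic participant.

    ``theta`` is the movement-independent individuality factor; it is
    the only subject-specific quantity the three domains share.
    """

    subject_id: int
    theta: np.ndarray      # (LATENT_DIM,), standard normal
    body_mass: float       # kg
    asymmetry: float       # right/left amplitude scale, ~1


@dataclass(frozen=True)
class DomainMap:
    """Linear read-out from the shared latent onto waveform parameters.

    ``params = clip(b + A @ theta + sigma_trial * tau * noise)`` where
    ``tau`` is the between-subject spread of each parameter, so
    ``sigma_trial`` is the within/between variation ratio.
    """

    domain: str
    A: np.ndarray               # (n_params, LATENT_DIM)
    b: np.ndarray               # (n_params,)
    tau: np.ndarray             # (n_params,) between-subject SDs
    sigma_trial: float
    lo: np.ndarray              # physical clamp, lower
    hi: np.ndarray              # physical clamp, upper
    param_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.sigma_trial < 0:
            raise ValueError("sigma_trial must be >= 0")

    def subject_params(self, subject: SubjectLatent) -> np.ndarray:
        """Noise-free parameter vector of a subject (the identity signature)."""
        return np.clip(self.b + self.A @ subject.theta, self.lo, self.hi)

    def draw_params(self, subject: SubjectLatent,
                    rng: np.random.Generator) -> np.ndarray:
        raw = (self.b + self.A @ subject.theta
               + self.sigma_trial * self.tau * rng.standard_normal(len(self.b)))
        return np.clip(raw, self.lo, self.hi)


@dataclass
class RawForceRecording:
    """Per-foot vertical GRF at 100 Hz with ground-truth stance intervals."""

    left: np.ndarray            # newtons
    right: np.ndarray
    body_mass: float            # kg
    condition: str              # slow / normal / fast
    ground_truth_contacts: dict  # {"left": [(start, end), ...], "right": [...]}
    sample_rate: int = FORCE_HZ


@dataclass
class RawPenRecording:
    """Vertical pen pressure at 200 Hz in device units (0-4095)."""

    pressure: np.ndarray
    condition: str
    ground_truth_letter_end: int  # exclusive end of the first letter
    sample_rate: int = PEN_HZ


def make_population(n_subjects: int, seed: int) -> list[SubjectLatent]:
    """Draw a deterministic synthetic cohort.

    Latents are standard normal; body mass is drawn around 68 +/- 9.3 kg
    (the cohort statistic being emulated).  Each subject is seeded from
    ``(seed, subject_id)``, so a subject's fields do not depend on the
    population size.
    """
    if n_subjects < 2:
        raise InvalidPopulationError(
            f"need at least 2 subjects for identification, got {n_subjects}")
    subjects = []
    for sid in range(n_subjects):
        rng = np.random.default_rng([seed, sid])
        theta = rng.standard_normal(LATENT_DIM)
        body_mass = float(np.clip(68.0 + 9.3 * rng.standard_normal(), 40.0, 120.0))
        asymmetry = float(np.clip(1.0 + 0.05 * rng.standard_normal(), 0.85, 1.15))
        subjects.append(SubjectLatent(sid, theta, body_mass, asymmetry))
    return subjects


# ---------------------------------------------------------------------------
# Domain maps

_WALK_PARAMS = dict(
    names=("amp1", "amp2", "valley", "t1", "t2", "stance_s", "duty"),
    b=[1.10, 1.12, 0.72, 0.25, 0.75, 0.64, 0.62],
    tau=[0.06, 0.06, 0.05, 0.015, 0.015, 0.04, 0.02],
    lo=[0.92, 0.92, 0.45, 0.15, 0.65, 0.45, 0.52],
    hi=[1.45, 1.45, 0.88, 0.35, 0.85, 0.90, 0.72],
)

_RUN_PARAMS = dict(
    names=("impact_amp", "active_amp", "t_impact", "t_active", "stance_s", "duty"),
    b=[1.60, 2.40, 0.10, 0.45, 0.30, 0.40],
    tau=[0.12, 0.15, 0.012, 0.02, 0.02, 0.02],
    lo=[1.15, 1.95, 0.06, 0.36, 0.22, 0.32],
    hi=[2.05, 2.90, 0.17, 0.54, 0.42, 0.48],
)

_WRITE_PARAMS = dict(
    names=("h1", "h2", "h3", "h4", "width_s", "gap1_s", "gap2_s", "gap3_s",
           "base_frac", "e_frac"),
    b=[2200.0, 1900.0, 2100.0, 1800.0, 0.040, 0.160, 0.170, 0.160,
       0.12, 0.55],
    tau=[260.0, 260.0, 260.0, 260.0, 0.005, 0.018, 0.018, 0.018,
         0.025, 0.05],
    lo=[1200.0, 1200.0, 1200.0, 1200.0, 0.028, 0.125, 0.125, 0.125,
        0.05, 0.22],
    hi=[3300.0, 3300.0, 3300.0, 3300.0, 0.048, 0.225, 0.225, 0.225,
        0.22, 0.75],
)


def _unit_rows(rng: np.random.Generator, n_params: int) -> np.ndarray:
    rows = rng.standard_normal((n_params, LATENT_DIM))
    return rows / np.linalg.norm(rows, axis=1, keepdims=True)


def make_domain_maps(master_seed: int = 0,
                     sigma_trial: float = 0.3) -> dict[str, DomainMap]:
    """Build the three linear latent-to-parameter read-outs.

    ``A`` rows are uniform unit directions scaled by the parameter's
    between-subject SD ``tau``, so each parameter has exactly variance
    ``tau**2`` across subjects.  ``sigma_trial`` sets the within-subject
    SD as a fraction of ``tau`` (default 0.3: trial scatter clearly
    smaller than subject separation, as identification studies assume).
    """
    maps = {}
    for domain, cfg in (("walking", _WALK_PARAMS),
                        ("running", _RUN_PARAMS),
                        ("writing", _WRITE_PARAMS)):
        rng = np.random.default_rng([master_seed, hash_domain(domain)])
        tau = np.asarray(cfg["tau"], dtype=float)
        A = _unit_rows(rng, len(tau)) * tau[:, None]
        maps[domain] = DomainMap(
            domain=domain,
            A=A,
            b=np.asarray(cfg["b"], dtype=float),
            tau=tau,
            sigma_trial=sigma_trial,
            lo=np.asarray(cfg["lo"], dtype=float),
            hi=np.asarray(cfg["hi"], dtype=float),
            param_names=tuple(cfg["names"]),
        )
    return maps


def hash_domain(domain: str) -> int:
    """Small stable per-domain integer for seed derivation."""
    return DOMAINS.index(domain) + 1


# ---------------------------------------------------------------------------
# Stance templates (in units of body weight, over normalized stance time)

def _walking_stance_bw(p: dict, n: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n)
    knots = [0.0, p["t1"], 0.5, p["t2"], 1.0]
    vals = [0.0, p["amp1"], p["valley"], p["amp2"], 0.0]
    return np.clip(PchipInterpolator(knots, vals)(u), 0.0, None)


def _running_stance_bw(p: dict, n: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n)
    t_imp, t_act = p["t_impact"], p["t_active"]
    t_dip = min(t_imp + 0.08, t_act - 0.05)
    knots = [0.0, t_imp, t_dip, t_act, 0.82, 1.0]
    vals = [0.0, p["impact_amp"], 0.88 * p["impact_amp"],
            p["active_amp"], 0.42 * p["active_amp"], 0.0]
    return np.clip(PchipInterpolator(knots, vals)(u), 0.0, None)


def _speed_adjust(params: dict, speed_factor: float) -> dict:
    """Faster locomotion: shorter stance/stride, modestly higher peaks."""
    out = dict(params)
    amp_scale = 1.0 + 0.25 * (speed_factor - 1.0)
    for key in ("amp1", "amp2", "valley", "impact_amp", "active_amp"):
        if key in out:
            out[key] *= amp_scale
    out["stance_s"] /= speed_factor
    return out


def _simulate_locomotion(template, subject: SubjectLatent, dmap: DomainMap,
                         speed_factor: float, n_strides: int,
                         seed: int) -> RawForceRecording:
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    condition = _condition_name(speed_factor)
    rng = np.random.default_rng([seed])

    base = dict(zip(dmap.param_names, dmap.subject_params(subject)))
    base = _speed_adjust(base, speed_factor)
    period = int(round(base["stance_s"] / base["duty"] * FORCE_HZ))
    lead = FORCE_HZ // 2  # half-second quiet lead-in / tail
    total = lead + n_strides * period + int(1.2 * period) + lead

    weight_n = subject.body_mass * GRAVITY
    channels = {"left": np.zeros(total), "right": np.zeros(total)}
    contacts = {"left": [], "right": []}
    offsets = {"left": 0, "right": period // 2}
    amp_scale = {"left": 1.0, "right": subject.asymmetry}

    for foot in ("left", "right"):
        for k in range(n_strides):
            p = dict(zip(dmap.param_names, dmap.draw_params(subject, rng)))
            p = _speed_adjust(p, speed_factor)
            n_stance = max(int(round(p["stance_s"] * FORCE_HZ)), 8)
            curve = template(p, n_stance) * amp_scale[foot] * weight_n
            start = lead + offsets[foot] + k * period
            channels[foot][start:start + n_stance] += curve
            above = np.flatnonzero(curve >= CONTACT_THRESHOLD_N)
            if above.size:
                contacts[foot].append(
                    (start + int(above[0]), start + int(above[-1]) + 1))

    return RawForceRecording(
        left=channels["left"], right=channels["right"],
        body_mass=subject.body_mass, condition=condition,
        ground_truth_contacts=contacts)


def _condition_name(speed_factor: float) -> str:
    for name, factor in SPEED_FACTORS.items():
        if abs(speed_factor - factor) < 1e-9:
            return name
    raise ValueError(f"speed_factor must be one of {sorted(SPEED_FACTORS.values())}")


def simulate_walking_recording(subject: SubjectLatent, dmap: DomainMap,
                               speed_factor: float = 1.0, n_strides: int = 1,
                               seed: int = 0) -> RawForceRecording:
    """Simulate a treadmill walking bout (double-peaked stance GRF)."""
    return _simulate_locomotion(_walking_stance_bw, subject, dmap,
                                speed_factor, n_strides, seed)


def simulate_running_recording(subject: SubjectLatent, dmap: DomainMap,
                               speed_factor: float = 1.0, n_strides: int = 1,
                               seed: int = 0) -> RawForceRecording:
    """Simulate a treadmill running bout (impact + active peak GRF)."""
    return _simulate_locomotion(_running_stance_bw, subject, dmap,
                                speed_factor, n_strides, seed)


# ---------------------------------------------------------------------------
# Handwriting

#: (amplitude multiplier, duration multiplier) per writing instruction
_INSTRUCTION_MODS = {
    "normal": (1.00, 1.00),
    "bigger": (1.30, 1.25),
    "smaller": (0.75, 0.80),
    "faster": (1.05, 0.70),
    "slower": (0.95, 1.40),
    "more beautiful": (1.00, 1.10),
}

_VALLEY_HALFWIDTH = 12   # samples; symmetric parabolic W-to-e valley
_EDGE_TAPER = 8          # samples of pen-down onset/offset ramp


def simulate_writing_trial(subject: SubjectLatent, dmap: DomainMap,
                           instruction: str = "normal", seed: int = 0,
                           attach_e: bool = False) -> RawPenRecording:
    """Simulate one handwriting trial (the first letter W, optionally + 'e').

    The W is four pressure humps on a positive pen-down baseline.  With
    ``attach_e`` the letter connects to a lower 'e' hump through an
    explicitly constructed symmetric pressure valley whose minimum
    sample is recorded as ``ground_truth_letter_end``; without it the
    recording ends after the fourth hump and ``ground_truth_letter_end``
    is one past the last nonzero sample.
    """
    if instruction not in _INSTRUCTION_MODS:
        raise ValueError(
            f"unknown instruction {instruction!r}; expected one of "
            f"{WRITING_INSTRUCTIONS}")
    amp_mult, dur_mult = _INSTRUCTION_MODS[instruction]
    rng = np.random.default_rng([seed])
    p = dict(zip(dmap.param_names, dmap.draw_params(subject, rng)))

    heights = np.array([p["h1"], p["h2"], p["h3"], p["h4"]]) * amp_mult
    width = p["width_s"] * dur_mult
    gaps = np.array([p["gap1_s"], p["gap2_s"], p["gap3_s"]]) * dur_mult
    # legibility: strokes must stay separable (distinct pressure humps)
    width = min(width, float(gaps.min()) / 3.4)
    gap = float(gaps[-1])  # spacing of the optional connected 'e'
    base = p["base_frac"] * heights.mean()

    pad = PEN_HZ // 4  # quiet pen-up lead-in / tail (exactly zero)
    t0 = 3.0 * width
    centers = t0 + np.concatenate([[0.0], np.cumsum(gaps)])

    def humps(tgrid: np.ndarray) -> np.ndarray:
        return base + sum(
            h * np.exp(-0.5 * ((tgrid - c) / width) ** 2)
            for h, c in zip(heights, centers))

    if not attach_e:
        n_w = int(round((centers[-1] + 3.0 * width) * PEN_HZ))
        idx = np.arange(n_w)
        ramp = np.minimum.reduce([np.full(n_w, 1.0),
                                  (idx + 1) / _EDGE_TAPER,
                                  (n_w - idx) / _EDGE_TAPER])
        letter = humps(idx / PEN_HZ) * ramp
        pressure = np.concatenate([np.zeros(pad), letter, np.zeros(pad)])
        pressure = np.clip(np.round(pressure), 0, PEN_MAX_LEVEL)
        nz = np.flatnonzero(pressure > 0)
        return RawPenRecording(pressure=pressure, condition=instruction,
                               ground_truth_letter_end=int(nz[-1]) + 1)

    # Connected 'e': keep the pen down past the 4th hump, descend through
    # an explicitly symmetric parabolic valley (unique minimum sample),
    # then rise into a lower 'e' hump.
    n_w = int(round((centers[-1] + 1.2 * width) * PEN_HZ))
    idx = np.arange(n_w)
    ramp = np.minimum(np.full(n_w, 1.0), (idx + 1) / _EDGE_TAPER)
    letter = humps(idx / PEN_HZ) * ramp

    v_min = max(0.4 * base, 30.0)
    v_edge = max(2.0 * base, v_min + 120.0)
    k = np.arange(-_VALLEY_HALFWIDTH, _VALLEY_HALFWIDTH + 1)
    valley = v_min + (v_edge - v_min) * (k / _VALLEY_HALFWIDTH) ** 2

    down = np.linspace(letter[-1], v_edge, max(int(0.8 * gap * PEN_HZ), 4),
                       endpoint=False)[1:]
    e_height = p["e_frac"] * heights.mean()
    n_e = int(round(6.0 * width * PEN_HZ))
    te = np.arange(n_e) / PEN_HZ
    e_part = base + e_height * np.exp(-0.5 * ((te - 3.0 * width) / width) ** 2)
    e_part = e_part * np.minimum(1.0, (n_e - np.arange(n_e)) / _EDGE_TAPER)
    up = np.linspace(v_edge, e_part[0], max(int(0.4 * gap * PEN_HZ), 4),
                     endpoint=False)[1:]

    pressure = np.concatenate(
        [np.zeros(pad), letter, down, valley, up, e_part, np.zeros(pad)])
    letter_end = pad + n_w + len(down) + _VALLEY_HALFWIDTH
    pressure = np.clip(np.round(pressure), 0, PEN_MAX_LEVEL)
    # rounding must not create ties at the valley minimum or zeros inside
    pressure[letter_end] = min(pressure[letter_end],
                               pressure[letter_end - 1] - 1,
                               pressure[letter_end + 1] - 1)
    nz_span = pressure[pad:-pad]
    nz_span[nz_span < 1] = 1.0
    return RawPenRecording(pressure=pressure, condition=instruction,
                           ground_truth_letter_end=int(letter_end))


# ---------------------------------------------------------------------------
# Delimited-text persistence (one row per sample + key-value sidecar)

def save_recording(rec, prefix, **extra_meta) -> tuple[Path, Path]:
    """Write a raw recording as CSV plus a key-value metadata sidecar.

    ``extra_meta`` (e.g. subject_id, domain, seed) is stored in the
    sidecar so a directory of recordings is self-describing.
    """
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".csv")
    meta_path = prefix.with_suffix(".meta")
    meta: dict[str, object] = {"sample_rate": rec.sample_rate,
                               "condition": rec.condition}
    meta.update(extra_meta)
    if isinstance(rec, RawForceRecording):
        n = len(rec.left)
        t = np.arange(n) / rec.sample_rate
        table = np.column_stack([t, rec.left, rec.right])
        header = "time_s,left_N,right_N"
        meta.update(kind="force", body_mass_kg=rec.body_mass,
                    ground_truth_contacts=rec.ground_truth_contacts)
    elif isinstance(rec, RawPenRecording):
        n = len(rec.pressure)
        t = np.arange(n) / rec.sample_rate
        table = np.column_stack([t, rec.pressure])
        header = "time_s,pressure"
        meta.update(kind="pen",
                    ground_truth_letter_end=rec.ground_truth_letter_end)
    else:
        raise TypeError(f"cannot save {type(rec).__name__}")
    np.savetxt(data_path, table, delimiter=",", header=header, comments="",
               fmt="%.6f")
    with open(meta_path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"{key}\t{json.dumps(value)}\n")
    return data_path, meta_path


def read_recording_meta(prefix) -> dict:
    """Parse the key-value sidecar of a saved recording."""
    meta = {}
    with open(Path(prefix).with_suffix(".meta")) as fh:
        for line in fh:
            key, _, value = line.rstrip("\n").partition("\t")
            meta[key] = json.loads(value)
    return meta


def load_recording(prefix):
    """Read back a recording written by :func:`save_recording`."""
    prefix = Path(prefix)
    meta = read_recording_meta(prefix)
    table = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1,
                       ndmin=2)
    if meta["kind"] == "force":
        contacts = {foot: [tuple(iv) for iv in ivs]
                    for foot, ivs in meta["ground_truth_contacts"].items()}
        return RawForceRecording(
            left=table[:, 1], right=table[:, 2],
            body_mass=meta["body_mass_kg"], condition=meta["condition"],
            ground_truth_contacts=contacts, sample_rate=meta["sample_rate"])
    return RawPenRecording(
        pressure=table[:, 1], condition=meta["condition"],
        ground_truth_letter_end=meta["ground_truth_letter_end"],
        sample_rate=meta["sample_rate"])
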