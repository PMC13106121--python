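"""Seeded synthetic sEMG cohort generator.

Emulates the study design of a standardized reach-to-grasp protocol: a cohort
of subjects, each performing several self-paced repetitions of the same
movement while eight upper-limb muscles are recorded with surface electrodes.
Each muscle's activation over the movement cycle is modelled as a sum of
Gaussian bursts (a burst template); a raw channel is that envelope multiplied
by band-limited Gaussian noise (the myoelectric carrier, ~20-450 Hz), plus
50 Hz power-line interference and a broadband noise floor.

The generator is deterministic given a seed: subject-level effects use the
substream (seed, 1, subject_index) and trial-level draws use
(seed, 2, subject_index, rep_index), so any single trial can be regenerated
without producing the whole cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .errors import ParameterError, SchemaError

#: Channel order used throughout: biceps brachii, triceps brachii, anterior
#: deltoid, trapezius, lateral deltoid, posterior deltoid, palmaris longus,
#: extensor carpi radialis.
MUSCLES: tuple[str, ...] = ("BB", "TB", "AD", "T", "LD", "PD", "PL", "ECR")

#: Illustrative movement-phase boundaries in % of cycle: reach/grasp, lift,
#: return, release. Used only to place default burst centers.
PHASE_BOUNDS: tuple[tuple[float, float], ...] = ((0, 30), (30, 55), (55, 80), (80, 100))


@dataclass(frozen=True)
class Burst:
    """One Gaussian activation burst: center/width in % of cycle, relative amplitude."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.center, self.width, self.amplitude]).all():
            raise ParameterError("burst parameters must be finite")
        if self.width <= 0:
            raise ParameterError(f"burst width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ParameterError(f"burst amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class BurstTemplate:
    """Activation template for one muscle: baseline plus Gaussian bursts over [0, 100]% cycle."""

    muscle: str
    bursts: tuple[Burst, ...]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if len(self.bursts) == 0:
            raise ParameterError(f"template for {self.muscle!r} needs at least one burst")
        if not np.isfinite(self.baseline) or self.baseline < 0:
            raise ParameterError(f"baseline must be finite and >= 0, got {self.baseline}")
        object.__setattr__(self, "bursts", tuple(self.bursts))


def eval_template(template: BurstTemplate, positions) -> np.ndarray:
    """Evaluate a burst template at cycle positions (in % of cycle, within [0, 100]).

    Returns ``baseline + sum_j amplitude_j * exp(-(p - center_j)^2 / (2 width_j^2))``,
    a finite non-negative curve.
    """
    p = np.asarray(positions, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 100.0):
        raise ParameterError("cycle positions must lie in [0, 100]")
    out = np.full(p.shape, float(template.baseline))
    for b in template.bursts:
        out += b.amplitude * np.exp(-((p - b.center) ** 2) / (2.0 * b.width**2))
    return out


def _default_templates() -> dict[str, BurstTemplate]:
    # Proximal shoulder muscles: large bursts early in the cycle (reach + lift);
    # elbow flexor/extensor peak during lift/return; distal wrist muscles carry
    # smaller, more numerous bursts (grasp, transport, release).
    return {
        "BB": BurstTemplate("BB", (Burst(35, 7, 1.0), Burst(68, 9, 0.55)), baseline=0.04),
        "TB": BurstTemplate("TB", (Burst(70, 8, 0.85), Burst(16, 8, 0.40)), baseline=0.05),
        "AD": BurstTemplate("AD", (Burst(20, 6, 1.0), Burst(46, 8, 0.70)), baseline=0.04),
        "T": BurstTemplate("T", (Burst(26, 8, 0.90), Burst(60, 9, 0.50)), baseline=0.06),
        "LD": BurstTemplate("LD", (Burst(22, 7, 0.90), Burst(50, 9, 0.50)), baseline=0.05),
        "PD": BurstTemplate("PD", (Burst(65, 8, 0.80), Burst(25, 9, 0.40)), baseline=0.05),
        "PL": BurstTemplate(
            "PL", (Burst(28, 7, 0.70), Burst(50, 8, 0.50), Burst(85, 7, 0.60)), baseline=0.06
        ),
        "ECR": BurstTemplate(
            "ECR", (Burst(25, 7, 0.80), Burst(55, 8, 0.60), Burst(82, 7, 0.50)), baseline=0.06
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """All generative parameters of a synthetic cohort.

    Amplitude perturbations are multiplicative lognormal factors (sigma on the
    log scale), applied per burst; timing perturbations shift burst centers and
    are expressed in % of the movement cycle. ``line_amp`` and ``noise_floor``
    are amplitudes relative to the muscle's nominal template peak.
    """

    n_subjects: int = 27
    n_reps: int = 5
    muscles: tuple[str, ...] = MUSCLES
    fs: float = 2148.0
    duration_range: tuple[float, float] = (2.0, 4.0)
    templates: Mapping[str, BurstTemplate] = field(default_factory=_default_templates)
    sigma_subject_amp: float = 1.1
    sigma_subject_time: float = 11.0
    sigma_trial_amp: float = 0.7
    sigma_trial_time: float = 7.0
    line_amp: float = 0.10
    noise_floor: float = 0.06
    seed: int = 20260923

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_reps < 2:
            raise ParameterError("cohort needs n_subjects >= 2 and n_reps >= 2")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ParameterError(f"invalid duration_range {self.duration_range}")
        if self.fs <= 900.0:
            raise ParameterError("fs must exceed 900 Hz (twice the 450 Hz band edge)")
        sigmas = (
            self.sigma_subject_amp,
            self.sigma_subject_time,
            self.sigma_trial_amp,
            self.sigma_trial_time,
            self.line_amp,
            self.noise_floor,
        )
        if not np.isfinite(sigmas).all() or min(sigmas) < 0:
            raise ParameterError("all sigma/amplitude parameters must be finite and >= 0")
        object.__setattr__(self, "muscles", tuple(self.muscles))
        missing = [m for m in self.muscles if m not in self.templates]
        if missing:
            raise ParameterError(f"missing templates for muscles: {missing}")


def make_default_spec() -> CohortSpec:
    """Default cohort mirroring the study design: 27 subjects x 8 muscles x 5 reps at 2148 Hz."""
    return CohortSpec()


@dataclass(frozen=True)
class TrialRecording:
    """Raw multi-channel sEMG for one subject x repetition.

    ``samples`` has shape (n_samples, n_channels), columns ordered as ``channels``.
    """

    subject_id: str
    rep_index: int
    fs: float
    channels: tuple[str, ...]
    samples: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(self.channels):
            raise SchemaError("samples must be 2-D with one column per channel")
        if self.fs <= 900.0:
            raise ParameterError("fs must exceed 900 Hz")
        if not np.isfinite(arr).all():
            raise ParameterError("trial samples must be finite")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.channels.index(name)]


def subject_label(subject_index: int) -> str:
    return f"S{subject_index + 1:02d}"


def draw_subject_effects(spec: CohortSpec, subject_index: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Draw per-subject, per-muscle burst perturbations from substream (seed, 1, subject)."""
    rng = np.random.default_rng([spec.seed, 1, subject_index])
    effects: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for m in spec.muscles:
        nb = len(spec.templates[m].bursts)
        gains = np.exp(rng.normal(0.0, spec.sigma_subject_amp, size=nb))
        shifts = rng.normal(0.0, spec.sigma_subject_time, size=nb)
        effects[m] = (gains, shifts)
    return effects


def _perturbed_template(
    template: BurstTemplate, gains: np.ndarray, shifts: np.ndarray
) -> BurstTemplate:
    bursts = tuple(
        Burst(b.center + s, b.width, b.amplitude * g)
        for b, g, s in zip(template.bursts, gains, shifts)
    )
    return BurstTemplate(template.muscle, bursts, template.baseline)


def _nominal_peak(template: BurstTemplate) -> float:
    return float(eval_template(template, np.linspace(0.0, 100.0, 201)).max())


def _carrier_sos(fs: float):
    return sps.butter(4, [20.0, min(450.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")


def generate_trial(
    spec: CohortSpec,
    subject_effects: Mapping[str, tuple[np.ndarray, np.ndarray]],
    subject_index: int,
    rep_index: int,
) -> TrialRecording:
    """Generate one raw trial; reproducible given (seed, subject_index, rep_index).

    ``rep_index`` is 1-based. Per muscle, the subject- and trial-perturbed burst
    template evaluated over the trial timeline is the target envelope; the raw
    channel is envelope x unit-RMS band-limited Gaussian carrier, plus 50 Hz
    interference at a random phase and a white-noise floor, both scaled by the
    muscle's nominal template peak.
    """
    if not 1 <= rep_index:
        raise ParameterError("rep_index is 1-based")
    rng = np.random.default_rng([spec.seed, 2, subject_index, rep_index])
    duration = rng.uniform(*spec.duration_range)
    n = max(int(round(duration * spec.fs)), 2)
    t = np.arange(n) / spec.fs
    pos = np.linspace(0.0, 100.0, n)
    sos = _carrier_sos(spec.fs)

    cols = []
    for m in spec.muscles:
        template = spec.templates[m]
        s_gains, s_shifts = subject_effects[m]
        nb = len(template.bursts)
        t_gains = np.exp(rng.normal(0.0, spec.sigma_trial_amp, size=nb))
        t_shifts = rng.normal(0.0, spec.sigma_trial_time, size=nb)
        pert = _perturbed_template(template, s_gains * t_gains, s_shifts + t_shifts)
        env = eval_template(pert, pos)

        white = rng.standard_normal(n)
        carrier = sps.sosfiltfilt(sos, white)
        rms = np.sqrt(np.mean(carrier**2))
        if rms > 0:
            carrier = carrier / rms
        phase = rng.uniform(0.0, 2.0 * np.pi)
        ref = _nominal_peak(template)
        channel = (
            env * carrier
            + spec.line_amp * ref * np.sin(2.0 * np.pi * 50.0 * t + phase)
            + spec.noise_floor * ref * rng.standard_normal(n)
        )
        cols.append(channel)

    return TrialRecording(
        subject_id=subject_label(subject_index),
        rep_index=rep_index,
        fs=spec.fs,
        channels=spec.muscles,
        samples=np.column_stack(cols),
    )


def generate_cohort(spec: CohortSpec) -> list[TrialRecording]:
    """Generate all n_subjects x n_reps trials of a cohort."""
    trials = []
    for si in range(spec.n_subjects):
        effects = draw_subject_effects(spec, si)
        for rep in range(1, spec.n_reps + 1):
            trials.append(generate_trial(spec, effects, si, rep))
    return trials


# ---------------------------------------------------------------------------
# On-disk contract: one delimited text file per trial (header = channel names),
# a manifest CSV, and the CohortSpec serialized as YAML.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9g"


def write_trial(trial: TrialRecording, path: Path) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        np.savetxt(
            fh,
            trial.samples,
            fmt=_FLOAT_FMT,
            delimiter=",",
            header=",".join(trial.channels),
            comments="",
        )


def read_trial(path: Path, subject_id: str, rep_index: int, fs: float) -> TrialRecording:
    df = pd.read_csv(path)
    return TrialRecording(
        subject_id=subject_id,
        rep_index=int(rep_index),
        fs=float(fs),
        channels=tuple(df.columns),
        samples=df.to_numpy(dtype=float),
    )


def spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["muscles"] = list(spec.muscles)
    d["duration_range"] = list(spec.duration_range)
    d["templates"] = {
        m: {
            "baseline": t.baseline,
            "bursts": [[b.center, b.width, b.amplitude] for b in t.bursts],
        }
        for m, t in spec.templates.items()
    }
    return d


def spec_from_dict(d: Mapping) -> CohortSpec:
    d = dict(d)
    if "templates" in d:
        d["templates"] = {
            m: BurstTemplate(m, tuple(Burst(*b) for b in td["bursts"]), td.get("baseline", 0.0))
            for m, td in d["templates"].items()
        }
    if "muscles" in d:
        d["muscles"] = tuple(d["muscles"])
    if "duration_range" in d:
        d["duration_range"] = tuple(d["duration_range"])
    return CohortSpec(**d)


def save_spec(spec: CohortSpec, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=True))


def load_spec(path: Path) -> CohortSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def write_cohort(spec: CohortSpec, out_dir: Path) -> pd.DataFrame:
    """Generate and write a cohort; returns the manifest (also written as CSV).

    The manifest records subject_id, rep_index, fs, n_samples and the trial file
    path relative to ``out_dir``; together with the serialized spec (seed
    included) it allows exact regeneration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trial_dir = out_dir / "trials"
    trial_dir.mkdir(exist_ok=True)
    rows = []
    for si in range(spec.n_subjects):
        effects = draw_subject_effects(spec, si)
        for rep in range(1, spec.n_reps + 1):
            trial = generate_trial(spec, effects, si, rep)
            rel = f"trials/{trial.subject_id}_rep{rep}.csv"
            write_trial(trial, out_dir / rel)
            rows.append(
                {
                    "subject_id": trial.subject_id,
                    "rep_index": rep,
                    "fs": spec.fs,
                    "n_samples": trial.n_samples,
                    "path": rel,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False, lineterminator="\n")
    save_spec(spec, out_dir / "cohort_spec.yaml")
    return manifest


def load_cohort(manifest_path: Path) -> list[TrialRecording]:
    """Read trials listed in a manifest CSV (paths resolved relative to the manifest)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "rep_index", "fs", "path"}
    if not required.issubset(manifest.columns):
        raise SchemaError(f"manifest must have columns {sorted(required)}")
    base = manifest_path.parent
    return [
        read_trial(base / row.path, row.subject_id, row.rep_index, row.fs)
        for row in manifest.itertuples()
    ]
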