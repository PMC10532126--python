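"""Synthetic low-resolution thermal facial video with a breathing nostril region.

Real recordings of this kind come from small LWIR camera modules (for
example 80 x 60 px at 8.7 Hz) that store radiation intensity as 14-bit
counts.  Air leaving the nostrils is warmer than inhaled ambient air, so the
mean intensity of a small region under the nose oscillates at the breathing
frequency.  This module generates sequences with exactly that structure: a
static, subject-specific face-like intensity template plus a periodic
modulation confined to a "nostril" rectangle, Gaussian sensor noise, and an
optional slow baseline drift.

The generator is the data source for every other module in the package
(window extraction, network training, the spectral baseline), so its output
is deliberately simple and fully characterised: with noise and drift
disabled, the region-of-interest mean equals ``baseline + amplitude *
waveform(2*pi*f*t + phase)`` up to integer quantisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "BreathingProfile",
    "ThermalSequence",
    "FormatError",
    "simulate_sequence",
    "write_sequence",
    "read_sequence",
    "make_cohort",
    "write_cohort",
    "read_cohort",
    "MAX_COUNT",
]

#: Largest representable intensity for a 14-bit sensor.
MAX_COUNT = 2**14 - 1

_WAVEFORMS = ("sinusoid", "asymmetric-exhale")


class FormatError(ValueError):
    """A persisted sequence is malformed; the message names the field."""


@dataclass(frozen=True)
class BreathingProfile:
    """Generative parameters of one synthetic breathing signal.

    Parameters
    ----------
    rr_bpm
        Respiratory rate in breaths per minute.  Must be positive unless
        ``amplitude`` is zero (a degenerate, non-breathing sequence).
    amplitude
        Peak modulation of the ROI-mean intensity, in sensor counts.
    phase
        Phase offset of the waveform, radians.
    waveform
        ``"sinusoid"`` (a cosine) or ``"asymmetric-exhale"`` (a skewed
        cosine with a faster falling edge, mimicking sharper exhalation
        peaks seen in real nostril signals).
    noise_sd
        Per-pixel Gaussian sensor noise standard deviation, counts.
    drift_per_s
        Slow additive baseline drift, counts per second.
    seed
        Seed for the noise generator; fixed seed gives bit-identical frames.
    """

    rr_bpm: float = 12.0
    amplitude: float = 600.0
    phase: float = 0.0
    waveform: str = "sinusoid"
    noise_sd: float = 20.0
    drift_per_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.amplitude > 0 and self.rr_bpm <= 0:
            raise ValueError(f"rr_bpm must be > 0, got {self.rr_bpm}")
        if self.waveform not in _WAVEFORMS:
            raise ValueError(
                f"waveform must be one of {_WAVEFORMS}, got {self.waveform!r}"
            )

    def waveform_values(self, t_s: np.ndarray) -> np.ndarray:
        """Evaluate the unit-amplitude waveform at times ``t_s`` (seconds)."""
        theta = 2.0 * np.pi * (self.rr_bpm / 60.0) * np.asarray(t_s) + self.phase
        if self.waveform == "sinusoid":
            return np.cos(theta)
        # Skewed cosine: phase modulation sharpens the falling (exhale) edge
        # while keeping the fundamental frequency and unit amplitude.
        return np.cos(theta + 0.5 * np.sin(theta))


@dataclass
class ThermalSequence:
    """A time-ordered stack of single-channel thermal frames.

    Attributes
    ----------
    frames
        ``(time, height, width)`` array of integer counts in
        ``[0, 2**14 - 1]`` (stored as uint16).
    fps
        Frame rate in Hz.
    subject_id
        Opaque identifier; all recordings of one volunteer share it.
    roi
        Nostril rectangle ``(row0, row1, col0, col1)``, 0-based half-open.
    gt_breaths
        Ground-truth number of breaths contained in the sequence
        (real-valued: ``rr_bpm * duration / 60``).
    """

    frames: np.ndarray
    fps: float
    subject_id: str
    roi: tuple[int, int, int, int]
    gt_breaths: float
    profile: BreathingProfile | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, h, w), got {self.frames.shape}")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.gt_breaths < 0:
            raise ValueError(f"gt_breaths must be >= 0, got {self.gt_breaths}")
        if self.frames.min() < 0 or self.frames.max() > MAX_COUNT:
            raise FormatError(
                f"frames: pixel values outside the 14-bit range [0, {MAX_COUNT}]"
            )
        r0, r1, c0, c1 = self.roi
        _, h, w = self.frames.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"roi {self.roi} outside frame bounds {(h, w)}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def rr_bpm(self) -> float:
        """Ground-truth rate in breaths per minute."""
        return self.gt_breaths * 60.0 / self.duration_s

    def roi_mean(self) -> np.ndarray:
        """Per-frame mean intensity over the nostril ROI (the raw breathing trace)."""
        r0, r1, c0, c1 = self.roi
        return self.frames[:, r0:r1, c0:c1].mean(axis=(1, 2))


def default_roi(resolution: tuple[int, int]) -> tuple[int, int, int, int]:
    """Lower-central "nostril" rectangle for a given (height, width)."""
    h, w = resolution
    rh = max(4, h // 8)
    rw = max(4, w // 8)
    r0 = min(int(0.60 * h), h - rh)
    c0 = (w - rw) // 2
    return (r0, r0 + rh, c0, c0 + rw)


def _face_template(resolution: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth warm-blob-on-cool-background intensity template (float counts)."""
    h, w = resolution
    rows = np.linspace(-1.0, 1.0, h)[:, None]
    cols = np.linspace(-1.0, 1.0, w)[None, :]
    # Slightly randomised blob geometry so each subject has its own face.
    cy = rng.uniform(-0.10, 0.10)
    cx = rng.uniform(-0.10, 0.10)
    sy = rng.uniform(0.55, 0.75)
    sx = rng.uniform(0.40, 0.60)
    background = rng.uniform(3500.0, 4500.0)
    face_peak = rng.uniform(4000.0, 5000.0)
    blob = np.exp(-(((rows - cy) / sy) ** 2 + ((cols - cx) / sx) ** 2))
    return background + face_peak * blob


def _roi_profile(roi: tuple[int, int, int, int]) -> np.ndarray:
    """Spatial weighting of the breathing modulation inside the ROI.

    Mean-one over the ROI so the ROI-mean trace carries exactly the nominal
    amplitude, but spatially non-uniform (an off-centre bump) so that
    shape-sensitive aggregators such as skewness also see the oscillation.
    """
    r0, r1, c0, c1 = roi
    rh, rw = r1 - r0, c1 - c0
    rows = np.linspace(-1.0, 1.0, rh)[:, None]
    cols = np.linspace(-1.0, 1.0, rw)[None, :]
    bump = np.exp(-(((rows - 0.2) / 0.8) ** 2 + ((cols + 0.4) / 0.6) ** 2))
    prof = 0.25 + bump
    return prof / prof.mean()


def simulate_sequence(
    profile: BreathingProfile,
    duration_s: float,
    fps: float,
    resolution: tuple[int, int] = (60, 80),
    subject_id: str = "sim",
    template: np.ndarray | None = None,
) -> ThermalSequence:
    """Generate one synthetic thermal breathing sequence.

    Parameters
    ----------
    profile
        Breathing-signal parameters.
    duration_s, fps
        Recording length (s) and frame rate (Hz); the frame count is
        ``round(duration_s * fps)``.
    resolution
        ``(height, width)`` in pixels; must admit a nostril ROI of at
        least 4 x 4 px.
    template
        Optional pre-built static face template (float counts) of the
        given resolution, e.g. a subject-specific one from `make_cohort`.

    Returns
    -------
    ThermalSequence
        Frames are integer counts clipped to the 14-bit range; the ROI-mean
        trace equals ``template-mean + amplitude * waveform + drift + noise``
        up to quantisation.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    h, w = resolution
    roi = default_roi((h, w))
    r0, r1, c0, c1 = roi
    if r1 > h or c1 > w or (r1 - r0) < 4 or (c1 - c0) < 4:
        raise ValueError(
            f"resolution {resolution} too small for a 4x4 nostril ROI (got {roi})"
        )

    rng = np.random.default_rng(profile.seed)
    if template is None:
        template = _face_template((h, w), rng)
    else:
        template = np.asarray(template, dtype=float)
        if template.shape != (h, w):
            raise ValueError(
                f"template shape {template.shape} != resolution {(h, w)}"
            )

    n = int(np.floor(duration_s * fps + 0.5))  # half-up: 15 s at 8.7 Hz -> 131
    t = np.arange(n) / fps
    wave = profile.waveform_values(t) if profile.amplitude > 0 else np.zeros(n)

    frames = np.broadcast_to(template, (n, h, w)).copy()
    prof = _roi_profile(roi)
    frames[:, r0:r1, c0:c1] += (
        profile.amplitude * wave[:, None, None] * prof[None, :, :]
    )
    if profile.drift_per_s != 0.0:
        frames += (profile.drift_per_s * t)[:, None, None]
    if profile.noise_sd > 0:
        frames += rng.normal(0.0, profile.noise_sd, size=frames.shape)

    # Round-half-to-even quantisation to integer counts, then clip to 14 bit.
    frames = np.clip(np.rint(frames), 0, MAX_COUNT).astype(np.uint16)

    gt_breaths = profile.rr_bpm * duration_s / 60.0 if profile.amplitude > 0 else 0.0
    return ThermalSequence(
        frames=frames,
        fps=fps,
        subject_id=subject_id,
        roi=roi,
        gt_breaths=gt_breaths,
        profile=profile,
    )


# ---------------------------------------------------------------------------
# Persistence: 16-bit multi-frame TIFF + JSON sidecar
# ---------------------------------------------------------------------------

_SIDECAR_FIELDS = ("subject_id", "fps", "roi", "gt_breaths")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_sequence(seq: ThermalSequence, path: str | Path) -> None:
    """Persist a sequence as 16-bit grayscale multi-frame TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seq.frames.astype(np.uint16))
    meta = {
        "subject_id": seq.subject_id,
        "fps": seq.fps,
        "roi": list(seq.roi),
        "gt_breaths": seq.gt_breaths,
        "profile": asdict(seq.profile) if seq.profile is not None else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_sequence(path: str | Path) -> ThermalSequence:
    """Read a sequence written by `write_sequence`; lossless round trip.

    Raises
    ------
    FormatError
        If the sidecar is missing a field or a pixel leaves the 14-bit range.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    frames = np.atleast_3d(frames)
    if frames.ndim == 2:  # single frame
        frames = frames[None]
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"sidecar metadata file not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _SIDECAR_FIELDS:
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing required field {key!r}")
    profile = None
    if meta.get("profile") is not None:
        profile = BreathingProfile(**meta["profile"])
    if frames.max() > MAX_COUNT:
        raise FormatError(
            f"frames: pixel value {int(frames.max())} exceeds 14-bit maximum {MAX_COUNT}"
        )
    return ThermalSequence(
        frames=frames,
        fps=float(meta["fps"]),
        subject_id=str(meta["subject_id"]),
        roi=tuple(int(v) for v in meta["roi"]),
        gt_breaths=float(meta["gt_breaths"]),
        profile=profile,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def make_cohort(
    n_subjects: int,
    recordings_per_subject: int = 1,
    rr_range: tuple[float, float] = (6.0, 30.0),
    fps: float = 8.7,
    duration_s: float = 15.0,
    seed: int = 0,
    resolution: tuple[int, int] = (60, 80),
    amplitude: float = 600.0,
    noise_sd: float = 20.0,
    drift_per_s: float = 0.0,
    waveform: str = "sinusoid",
) -> list[ThermalSequence]:
    """Simulate a cohort of subjects, each with its own face template.

    Per-recording respiratory rate is drawn uniformly from ``rr_range`` and
    phase uniformly from ``[0, 2*pi)``.  Deterministic under ``seed``.  The
    defaults mirror a small LWIR study population: 15-second recordings at
    8.7 Hz, 80 x 60 px, resting rates between 6 and 30 breaths/min.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    if recordings_per_subject < 1:
        raise ValueError(
            f"recordings_per_subject must be >= 1, got {recordings_per_subject}"
        )
    lo, hi = rr_range
    if not lo < hi:
        raise ValueError(f"rr_range must satisfy low < high, got {rr_range}")

    master = np.random.default_rng(seed)
    cohort: list[ThermalSequence] = []
    for s in range(n_subjects):
        subject_id = f"S{s:03d}"
        template = _face_template(resolution, master)
        for _ in range(recordings_per_subject):
            rr = master.uniform(lo, hi)
            phase = master.uniform(0.0, 2.0 * np.pi)
            noise_seed = int(master.integers(0, 2**31 - 1))
            prof = BreathingProfile(
                rr_bpm=rr,
                amplitude=amplitude,
                phase=phase,
                waveform=waveform,
                noise_sd=noise_sd,
                drift_per_s=drift_per_s,
                seed=noise_seed,
            )
            cohort.append(
                simulate_sequence(
                    prof, duration_s, fps, resolution,
                    subject_id=subject_id, template=template,
                )
            )
    return cohort


def write_cohort(cohort: list[ThermalSequence], out_dir: str | Path) -> Path:
    """Write every sequence plus a CSV manifest; returns the manifest path."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seq in enumerate(cohort):
        rel = f"{seq.subject_id}_r{i:03d}.tif"
        write_sequence(seq, out_dir / rel)
        rows.append(
            {
                "subject_id": seq.subject_id,
                "path": rel,
                "fps": seq.fps,
                "duration_s": seq.duration_s,
                "gt_breaths": seq.gt_breaths,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: str | Path) -> list[ThermalSequence]:
    """Load every sequence listed in a cohort manifest CSV."""
    import pandas as pd

    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    return [read_sequence(manifest.parent / rel) for rel in df["path"]]
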