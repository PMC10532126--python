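"""Sliding-window extraction and two-pathway temporal subsampling.

A recording is resampled to a target frame rate, cut into fixed-length
windows (overlapping by all but a configurable stride, typically one
second), and each window is turned into the pair of temporally subsampled
views consumed by the two branches of the network: a dense view taking
every ``alpha``-th frame and a sparse view taking every ``beta``-th frame.
With a 128-frame window, ``alpha=4`` and ``beta=16`` these are 32- and
8-frame clips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import MAX_COUNT, ThermalSequence

__all__ = [
    "WindowSpec",
    "ClipPair",
    "resample_fps",
    "extract_windows",
    "subsample_paths",
    "prepare_clip",
    "sequence_to_clips",
]


@dataclass(frozen=True)
class WindowSpec:
    """Geometry of the window extraction and the network input.

    ``window_len_frames`` is the sliding-window size in frames (64 or 128 in
    the swept configurations; any positive value is accepted),
    ``stride_frames`` the hop between window starts, ``target_fps`` the rate
    recordings are resampled to before windowing, and ``out_height`` /
    ``out_width`` / ``channels`` the spatial size and channel count each
    frame is resized/replicated to.
    """

    window_len_frames: int = 128
    stride_frames: int = 8
    target_fps: float = 8.0
    out_height: int = 224
    out_width: int = 224
    channels: int = 3

    def __post_init__(self) -> None:
        if self.window_len_frames < 1:
            raise ValueError(f"window_len_frames must be >= 1, got {self.window_len_frames}")
        if self.stride_frames < 1:
            raise ValueError(f"stride_frames must be >= 1, got {self.stride_frames}")
        if self.target_fps <= 0:
            raise ValueError(f"target_fps must be > 0, got {self.target_fps}")
        if self.out_height < 1 or self.out_width < 1 or self.channels < 1:
            raise ValueError("output geometry must be positive")


@dataclass
class ClipPair:
    """One training example: the two pathway views of a window plus its label.

    ``dense_view`` is the ``alpha``-strided view with ``Ws/alpha`` frames,
    ``sparse_view`` the ``beta``-strided view with ``Ws/beta`` frames; both
    are ``(channels, time, height, width)`` float32 arrays in [0, 1].
    """

    dense_view: np.ndarray
    sparse_view: np.ndarray
    label_rr: float
    subject_id: str

    def __post_init__(self) -> None:
        if self.dense_view.ndim != 4 or self.sparse_view.ndim != 4:
            raise ValueError("views must be 4-D (c, t, h, w)")
        if self.dense_view.shape[0] != self.sparse_view.shape[0]:
            raise ValueError("views must share channel count")
        if self.dense_view.shape[2:] != self.sparse_view.shape[2:]:
            raise ValueError("views must share spatial size")


def resample_fps(seq: ThermalSequence, target_fps: float) -> ThermalSequence:
    """Resample a sequence to ``target_fps`` by nearest-frame index selection.

    No interpolation: the output frame at time ``k / target_fps`` is the
    input frame whose timestamp is nearest.  ``gt_breaths`` is unchanged.
    """
    if target_fps <= 0:
        raise ValueError(f"target_fps must be > 0, got {target_fps}")
    if target_fps == seq.fps:
        return seq
    n_in = seq.n_frames
    n_out = int(np.floor(n_in * target_fps / seq.fps + 0.5))
    idx = np.clip(np.rint(np.arange(n_out) * seq.fps / target_fps).astype(int), 0, n_in - 1)
    return ThermalSequence(
        frames=seq.frames[idx],
        fps=target_fps,
        subject_id=seq.subject_id,
        roi=seq.roi,
        gt_breaths=seq.gt_breaths,
        profile=seq.profile,
    )


def extract_windows(
    seq: ThermalSequence, spec: WindowSpec
) -> list[tuple[np.ndarray, float]]:
    """Cut a sequence into overlapping windows with the sequence's RR label.

    Windows start at multiples of ``stride_frames``; a sequence shorter than
    the window yields an empty list.  The label of every window is the
    parent sequence's rate in breaths per minute (the simulated rate is
    constant over a recording).
    """
    ws = spec.window_len_frames
    t = seq.n_frames
    if t < ws:
        return []
    label = seq.rr_bpm
    starts = range(0, t - ws + 1, spec.stride_frames)
    return [(seq.frames[s : s + ws], label) for s in starts]


def subsample_paths(
    window: np.ndarray, alpha: int, beta: int
) -> tuple[np.ndarray, np.ndarray]:
    """Build the dense (every ``alpha``-th frame) and sparse (every
    ``beta``-th frame) views of a window, both anchored at frame 0.

    Both strides must divide the window length exactly and ``alpha <= beta``.
    """
    ws = window.shape[0]
    for name, stride in (("alpha", alpha), ("beta", beta)):
        if stride < 1 or ws % stride != 0:
            raise ValueError(
                f"{name}={stride} does not divide window length Ws={ws}"
            )
    if alpha > beta:
        raise ValueError(f"alpha ({alpha}) must be <= beta ({beta})")
    return window[::alpha], window[::beta]


def _resize_frames(frames: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bicubic spatial resize of a (t, h, w) float stack."""
    if frames.shape[1:] == out_hw:
        return frames
    from skimage.transform import resize

    return resize(
        frames,
        (frames.shape[0], *out_hw),
        order=3,
        mode="edge",
        anti_aliasing=frames.shape[1] > out_hw[0] or frames.shape[2] > out_hw[1],
        preserve_range=True,
    ).astype(np.float32)


def prepare_clip(
    window: np.ndarray,
    spec: WindowSpec,
    alpha: int,
    beta: int,
    label_rr: float,
    subject_id: str = "",
) -> ClipPair:
    """Normalise, resize and subsample one window into a `ClipPair`.

    Counts are scaled by ``1 / (2**14 - 1)`` to [0, 1], frames are resized
    bicubically to the spec's output size, the single channel is replicated
    to ``spec.channels``, and both pathway views are cut with
    `subsample_paths`.
    """
    frames = np.asarray(window, dtype=np.float32) / MAX_COUNT
    frames = _resize_frames(frames, (spec.out_height, spec.out_width))
    dense, sparse = subsample_paths(frames, alpha, beta)

    def to_chw(view: np.ndarray) -> np.ndarray:
        out = np.repeat(view[None], spec.channels, axis=0)
        return np.ascontiguousarray(out, dtype=np.float32)

    return ClipPair(
        dense_view=to_chw(dense),
        sparse_view=to_chw(sparse),
        label_rr=float(label_rr),
        subject_id=subject_id,
    )


def sequence_to_clips(
    seq: ThermalSequence, spec: WindowSpec, alpha: int, beta: int
) -> list[ClipPair]:
    """Resample, window and clip one sequence end to end."""
    seq = resample_fps(seq, spec.target_fps)
    return [
        prepare_clip(win, spec, alpha, beta, label, seq.subject_id)
        for win, label in extract_windows(seq, spec)
    ]
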