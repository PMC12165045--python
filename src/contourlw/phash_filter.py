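"""Perceptual-hash near-duplicate frame filtering.

A frame is reduced to a 64-bit signature: grayscale, bilinear resize to
32 x 32, orthonormal type-II 2-D DCT, keep the top-left 8 x 8 low-frequency
block, threshold each coefficient against the block mean. Streams are
deduplicated by Hamming distance between consecutive signatures with an
empirical threshold tau = 15.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image
from scipy.fft import dctn

__all__ = [
    "compute_phash",
    "hamming_distance",
    "filter_similar_frames",
    "dedup_directory",
    "DEFAULT_TAU",
]

DEFAULT_TAU = 15

# ITU-R 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray32(image) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    elif arr.ndim != 2:
        raise ValueError("expected a 2-D or 3-D image array")
    im = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(im.resize((32, 32), Image.BILINEAR), dtype=np.float64)


def compute_phash(image) -> np.ndarray:
    """64-bit perceptual hash of an image, returned as a (64,) 0/1 array."""
    small = _to_gray32(image)
    coeffs = dctn(small, type=2, norm="ortho")
    block = coeffs[:8, :8]
    mu = block.mean()
    return (block > mu).astype(np.uint8).flatten()


def hamming_distance(h1, h2) -> int:
    h1 = np.asarray(h1, dtype=np.uint8)
    h2 = np.asarray(h2, dtype=np.uint8)
    if h1.shape != (64,) or h2.shape != (64,):
        raise ValueError("hashes must be 64 bits")
    return int(np.count_nonzero(h1 != h2))


def filter_similar_frames(stream, tau: int = DEFAULT_TAU, compare_to_retained: bool = True):
    """Drop near-duplicate frames from an ordered (frame_id, image) stream.

    Each incoming frame is hashed and compared with the reference hash; if
    the Hamming distance is <= tau, the frame is dropped. By default the
    reference is the last *retained* frame so a slow drift cannot be
    collapsed forever; with ``compare_to_retained=False`` the raw previous
    frame is the reference instead. The first frame is always retained.
    """
    if not 0 <= tau <= 64:
        raise ValueError("tau must be in [0, 64]")
    kept = []
    ref_hash = None
    for frame_id, image in stream:
        h = compute_phash(image)
        if ref_hash is None or hamming_distance(h, ref_hash) > tau:
            kept.append((frame_id, image))
            ref_hash = h
        elif not compare_to_retained:
            ref_hash = h
    return kept


def dedup_directory(in_dir, out_dir, tau: int = DEFAULT_TAU) -> dict:
    """Deduplicate the PNG frames of a directory (sorted by filename)."""
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = sorted(in_dir.glob("*.png"))
    stream = ((p.name, np.asarray(Image.open(p))) for p in frames)
    kept = filter_similar_frames(stream, tau=tau)
    for name, image in kept:
        Image.fromarray(np.asarray(image).astype(np.uint8)).save(out_dir / name)
    return {"total": len(frames), "kept": len(kept), "dropped": len(frames) - len(kept)}
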