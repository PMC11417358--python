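"""Whole-map prediction from a trained (or oracle) network.

The pipeline mirrors training preprocessing: resample the input map onto
the 0.7 Å working grid, tile it into overlapping 32-cubes with a margin,
classify each cube, average overlapping contributions, and re-interpolate
the result back onto the input map's own grid.  Because every interior
point is covered by several cubes (8 with the default overlap), averaging
binary per-cube classifications yields values between 0 and 1, and the
spread of those per-cube votes gives a point-wise variance map.
"""

from __future__ import annotations

import numpy as np

from .chunks import (CHUNK_EDGE, CHUNK_OVERLAP, extract_chunks, reassemble,
                     reassemble_variance)
from .maps import (DEFAULT_SPACING, DensityMap, OrthoGrid,
                   interpolate_from_ortho, interpolate_to_ortho)

MODES = ("argmax", "raw", "variance")


class OracleNetwork:
    """A stand-in network that answers with the ground-truth target map.

    Used to validate the inference plumbing end to end: fed the true
    binary target for every cube, the reassembled prediction must
    reproduce the target map itself.
    """

    def __init__(self, target: OrthoGrid, margin: int = CHUNK_OVERLAP):
        self.padded = np.pad(target.values, margin, mode="constant")

    def predict_proba(self, chunk_values: np.ndarray,
                      origins=None) -> np.ndarray:
        if origins is None:
            raise ValueError("the oracle needs chunk origins")
        e = chunk_values.shape[1]
        out = np.zeros(chunk_values.shape + (2,))
        for b, (i, j, k) in enumerate(origins):
            block = np.zeros((e, e, e))
            src = self.padded[i:i + e, j:j + e, k:k + e]
            block[:src.shape[0], :src.shape[1], :src.shape[2]] = src
            out[b, ..., 1] = block
            out[b, ..., 0] = 1.0 - block
        return out


def classify_chunk(probabilities: np.ndarray, mode: str = "argmax"
                   ) -> np.ndarray:
    """Reduce a (e, e, e, 2) probability cube to a single-channel cube.

    argmax: 1 where the positive channel is >= 0.5, else 0.
    raw: the positive-channel probability unchanged.
    """
    pos = probabilities[..., 1]
    if mode == "argmax":
        return (pos >= 0.5).astype(float)
    if mode in ("raw", "variance"):
        return np.asarray(pos, dtype=float)
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def _chunk_classifications(ortho: OrthoGrid, network, mode: str,
                           chunk_edge: int, overlap: int, margin: int,
                           batch_size: int = 8):
    chunkset = extract_chunks(ortho, chunk_edge=chunk_edge, overlap=overlap,
                              margin=margin)
    outputs: list[np.ndarray] = []
    for start in range(0, len(chunkset), batch_size):
        batch = chunkset.chunks[start:start + batch_size]
        values = np.asarray([c.values for c in batch])
        origins = [c.origin_index for c in batch]
        probs = network.predict_proba(values, origins=origins)
        # variance mode aggregates the same per-chunk classifications as
        # standard inference (argmax votes)
        cls_mode = "argmax" if mode == "variance" else mode
        for b in range(len(batch)):
            outputs.append(classify_chunk(probs[b], cls_mode))
    return chunkset, outputs


def predict(dmap: DensityMap, network, mode: str = "argmax",
            spacing: float = DEFAULT_SPACING,
            chunk_edge: int = CHUNK_EDGE, overlap: int = CHUNK_OVERLAP,
            batch_size: int = 8) -> DensityMap:
    """Predict a group probability map on the input map's grid."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if network is None or not hasattr(network, "predict_proba"):
        raise ValueError("a trained network with predict_proba is required")
    ortho = interpolate_to_ortho(dmap, spacing=spacing)
    chunkset, outputs = _chunk_classifications(
        ortho, network, mode, chunk_edge, overlap, margin=overlap,
        batch_size=batch_size)
    if mode == "variance":
        merged = reassemble_variance(chunkset, outputs)
    else:
        merged = reassemble(chunkset, outputs)
    return interpolate_from_ortho(merged, dmap)


def predict_ortho(dmap: DensityMap, network, mode: str = "argmax",
                  spacing: float = DEFAULT_SPACING,
                  chunk_edge: int = CHUNK_EDGE,
                  overlap: int = CHUNK_OVERLAP,
                  batch_size: int = 8) -> OrthoGrid:
    """As :func:`predict` but returning the working-grid result directly."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    ortho = interpolate_to_ortho(dmap, spacing=spacing)
    chunkset, outputs = _chunk_classifications(
        ortho, network, mode, chunk_edge, overlap, margin=overlap,
        batch_size=batch_size)
    if mode == "variance":
        return reassemble_variance(chunkset, outputs)
    return reassemble(chunkset, outputs)


def predict_variance(dmap: DensityMap, network,
                     spacing: float = DEFAULT_SPACING,
                     batch_size: int = 8) -> DensityMap:
    """Point-wise population variance of the per-cube classifications."""
    return predict(dmap, network, mode="variance", spacing=spacing,
                   batch_size=batch_size)
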