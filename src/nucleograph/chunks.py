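"""Overlapping-chunk decomposition of an orthogonal grid.

The working grid is zero-padded by a margin, tiled into cubes of edge 32
with a 16-point overlap between consecutive cubes (stride 16), run through
the network cube by cube, and reassembled by averaging every contribution
covering each point.  The margin guarantees that points near the data
boundary are still predicted more than once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import OrthoGrid

CHUNK_EDGE = 32
CHUNK_OVERLAP = 16


@dataclass
class Chunk:
    values: np.ndarray  # (edge, edge, edge)
    origin_index: tuple[int, int, int]  # corner in the padded parent grid


@dataclass
class ChunkSet:
    chunks: list[Chunk]
    parent_shape: tuple[int, int, int]  # unpadded grid shape
    padded_shape: tuple[int, int, int]
    chunk_edge: int = CHUNK_EDGE
    stride: int = CHUNK_EDGE - CHUNK_OVERLAP
    margin: int = CHUNK_OVERLAP
    spacing: float = 0.7
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __len__(self) -> int:
        return len(self.chunks)


def _axis_origins(padded_n: int, edge: int, stride: int) -> list[int]:
    """Chunk corner indices along one axis; last chunk clamped to the end."""
    if padded_n <= edge:
        return [0]
    origins = list(range(0, padded_n - edge + 1, stride))
    if origins[-1] + edge < padded_n:
        origins.append(padded_n - edge)
    return origins


def extract_chunks(grid: OrthoGrid, chunk_edge: int = CHUNK_EDGE,
                   overlap: int = CHUNK_OVERLAP,
                   margin: int = CHUNK_OVERLAP) -> ChunkSet:
    """Zero-pad the grid and tile it into overlapping cubes."""
    if not (chunk_edge > overlap >= 0):
        raise ValueError("require chunk_edge > overlap >= 0")
    if min(grid.shape) < 1:
        raise ValueError("grid must have at least one point per axis")
    stride = chunk_edge - overlap
    padded = np.pad(grid.values, margin, mode="constant")
    # ensure the padded block can hold at least one chunk
    grow = [max(0, chunk_edge - s) for s in padded.shape]
    if any(grow):
        padded = np.pad(padded, [(0, g) for g in grow], mode="constant")
    axes = [_axis_origins(n, chunk_edge, stride) for n in padded.shape]
    chunks = [
        Chunk(values=padded[i:i + chunk_edge, j:j + chunk_edge,
                            k:k + chunk_edge].copy(),
              origin_index=(i, j, k))
        for i in axes[0] for j in axes[1] for k in axes[2]
    ]
    return ChunkSet(chunks=chunks, parent_shape=grid.shape,
                    padded_shape=padded.shape, chunk_edge=chunk_edge,
                    stride=stride, margin=margin, spacing=grid.spacing,
                    origin=grid.origin.copy())


def reassemble(chunkset: ChunkSet,
               per_chunk_outputs: list[np.ndarray]) -> OrthoGrid:
    """Average per-chunk outputs back onto the unpadded parent grid.

    Every parent point's value is the arithmetic mean over all chunks
    covering it; contribution counts are tracked per point so clamped edge
    chunks are averaged exactly.
    """
    if len(per_chunk_outputs) != len(chunkset.chunks):
        raise ValueError(
            f"got {len(per_chunk_outputs)} outputs for "
            f"{len(chunkset.chunks)} chunks")
    e = chunkset.chunk_edge
    acc = np.zeros(chunkset.padded_shape)
    counts = np.zeros(chunkset.padded_shape)
    lo = np.full(chunkset.padded_shape, np.inf)
    hi = np.full(chunkset.padded_shape, -np.inf)
    for chunk, out in zip(chunkset.chunks, per_chunk_outputs):
        out = np.asarray(out, dtype=float)
        if out.shape != (e, e, e):
            raise ValueError(f"chunk output shape {out.shape} != {(e, e, e)}")
        i, j, k = chunk.origin_index
        sl = (slice(i, i + e), slice(j, j + e), slice(k, k + e))
        acc[sl] += out
        counts[sl] += 1.0
        np.minimum(lo[sl], out, out=lo[sl])
        np.maximum(hi[sl], out, out=hi[sl])
    uncovered = counts == 0
    counts[uncovered] = 1.0
    lo[uncovered] = 0.0
    hi[uncovered] = 0.0
    # clipping to the contribution range keeps the mean exact where all
    # contributions agree (odd counts would otherwise round)
    mean = np.clip(acc / counts, lo, hi)
    m = chunkset.margin
    nx, ny, nz = chunkset.parent_shape
    return OrthoGrid(values=mean[m:m + nx, m:m + ny, m:m + nz],
                     spacing=chunkset.spacing,
                     origin=chunkset.origin.copy())


def reassemble_variance(chunkset: ChunkSet,
                        per_chunk_outputs: list[np.ndarray]) -> OrthoGrid:
    """Population variance of the per-chunk outputs covering each point."""
    if len(per_chunk_outputs) != len(chunkset.chunks):
        raise ValueError(
            f"got {len(per_chunk_outputs)} outputs for "
            f"{len(chunkset.chunks)} chunks")
    e = chunkset.chunk_edge
    s1 = np.zeros(chunkset.padded_shape)
    s2 = np.zeros(chunkset.padded_shape)
    counts = np.zeros(chunkset.padded_shape)
    for chunk, out in zip(chunkset.chunks, per_chunk_outputs):
        out = np.asarray(out, dtype=float)
        i, j, k = chunk.origin_index
        s1[i:i + e, j:j + e, k:k + e] += out
        s2[i:i + e, j:j + e, k:k + e] += out * out
        counts[i:i + e, j:j + e, k:k + e] += 1.0
    counts[counts == 0] = 1.0
    var = s2 / counts - (s1 / counts) ** 2
    var = np.maximum(var, 0.0)  # guard tiny negative rounding
    m = chunkset.margin
    nx, ny, nz = chunkset.parent_shape
    return OrthoGrid(values=var[m:m + nx, m:m + ny, m:m + nz],
                     spacing=chunkset.spacing,
                     origin=chunkset.origin.copy())
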