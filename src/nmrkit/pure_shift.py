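"""Pure shift FID reconstruction from interferogram (pseudo-2D) raw data.

Interferogram pure shift experiments acquire short homodecoupled data
"chunks" in successive increments; concatenating the chunks yields a
synthetic 1D FID whose transform shows singlets free of J-multiplet
structure.  ``drop_points`` lead-in samples are discarded from the start
of every chunk (including the first — ``first_chunk`` counts the points
*kept* from increment one, a documented composition choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FidSet

__all__ = ["PureShiftParams", "reconstruct"]


@dataclass
class PureShiftParams:
    """Geometry of an interferogram acquisition.

    ``chunks``: increments used; ``chunk_points``: data points per chunk;
    ``first_chunk``: points kept from the first increment; ``drop_points``:
    points discarded from the start of each chunk.  ``chunk_duration`` (s)
    may be given instead of ``chunk_points`` when a dwell is known:
    ``chunk_points = round(chunk_duration / dwell)``.
    """

    chunks: int
    chunk_points: int
    first_chunk: int | None = None
    drop_points: int = 0

    def __post_init__(self) -> None:
        if self.first_chunk is None:
            self.first_chunk = self.chunk_points
        if self.chunks < 1 or self.chunk_points < 1 or self.first_chunk < 1:
            raise ValueError("chunks, chunk_points and first_chunk must be >= 1")
        if self.drop_points < 0:
            raise ValueError("drop_points must be >= 0")

    @classmethod
    def from_duration(
        cls, chunks: int, chunk_duration: float, dwell: float,
        first_chunk: int | None = None, drop_points: int = 0,
    ) -> "PureShiftParams":
        return cls(chunks, int(round(chunk_duration / dwell)), first_chunk, drop_points)

    @classmethod
    def from_meta(cls, fid: FidSet) -> "PureShiftParams":
        """Read the geometry stored with simulator-generated raw data."""
        ps = fid.meta.get("pureshift")
        if ps is None:
            raise ValueError("no pure shift parameters in FidSet metadata")
        return cls(ps["chunks"], ps["chunk_points"], ps["first_chunk"], ps["drop_points"])

    @property
    def output_length(self) -> int:
        return self.first_chunk + (self.chunks - 1) * self.chunk_points


def reconstruct(raw: FidSet, params: PureShiftParams | None = None) -> FidSet:
    """Concatenate chunks into the 1D pure shift FID.

    ``output = concat(inc_1[drop : drop+first_chunk],
    inc_2[drop : drop+chunk_points], ...)``; length
    ``first_chunk + (chunks-1)*chunk_points``; dwell preserved.
    """
    if params is None:
        params = PureShiftParams.from_meta(raw)
    if raw.n_increments < params.chunks:
        raise ValueError(
            f"raw data has {raw.n_increments} increments, need {params.chunks}"
        )
    pieces = []
    for r in range(params.chunks):
        length = params.first_chunk if r == 0 else params.chunk_points
        end = params.drop_points + length
        if raw.n_points < end:
            raise ValueError(
                f"increment {r + 1} has {raw.n_points} points, "
                f"needs {end} (drop_points + chunk length)"
            )
        pieces.append(raw.data[r, params.drop_points : end])
    out = np.concatenate(pieces)
    return FidSet(
        data=out[None, :],
        dwell=raw.dwell,
        sfrq=raw.sfrq,
        ref_offset_hz=raw.ref_offset_hz,
        meta={**raw.meta, "pureshift_reconstructed": True},
    )
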