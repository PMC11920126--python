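"""Rating-contingency counts: the sufficient statistic for all SDT fitting.

A :class:`RatingCounts` table holds trial counts indexed by
(stimulus, type-1 response, rating).  The stimulus and response axes are
binary -- ``nonmatch`` (noise, S1) and ``match`` (signal, S2) -- and the
rating axis has ``K >= 2`` ordered levels (K = 2 for the binary pre-rating
phase, K = 5 for the post-rating confidence phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STIMULI = ("nonmatch", "match")
RESPONSES = ("nonmatch", "match")


@dataclass(frozen=True)
class RatingCounts:
    """Stimulus x response x rating contingency counts.

    Parameters
    ----------
    counts
        Integer array of shape ``(2, 2, K)``: axis 0 is the stimulus class
        (0 = nonmatch, 1 = match), axis 1 the type-1 response with the same
        coding, axis 2 the rating level (index ``k`` holds rating ``k + 1``).
    """

    counts: np.ndarray = field()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 3 or arr.shape[:2] != (2, 2):
            raise ValueError(f"counts must have shape (2, 2, K), got {arr.shape}")
        if arr.shape[2] < 2:
            raise ValueError(f"need K >= 2 rating levels, got K={arr.shape[2]}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def k(self) -> int:
        """Number of rating levels."""
        return self.counts.shape[2]

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    def stimulus_totals(self) -> np.ndarray:
        """Trials per stimulus class, shape (2,)."""
        return self.counts.sum(axis=(1, 2))

    @classmethod
    def from_trials(
        cls,
        stimulus: np.ndarray,
        response: np.ndarray,
        rating: np.ndarray,
        k: int,
    ) -> "RatingCounts":
        """Tabulate per-trial labels into a counts table.

        ``stimulus`` and ``response`` are arrays of ``"nonmatch"``/``"match"``
        labels (or 0/1 integers); ``rating`` holds integer levels in
        ``1..k``.
        """
        stim = _binary_index(stimulus, "stimulus")
        resp = _binary_index(response, "response")
        rat = np.asarray(rating, dtype=np.int64)
        if ((rat < 1) | (rat > k)).any():
            bad = rat[(rat < 1) | (rat > k)][0]
            raise ValueError(f"rating {bad} outside 1..{k}")
        counts = np.zeros((2, 2, k), dtype=np.int64)
        np.add.at(counts, (stim, resp, rat - 1), 1)
        return cls(counts)

    def to_frame(self) -> pd.DataFrame:
        """Flat long-format table (stimulus, response, rating, count)."""
        s, r, k = np.meshgrid(
            np.arange(2), np.arange(2), np.arange(1, self.k + 1), indexing="ij"
        )
        return pd.DataFrame(
            {
                "stimulus": np.take(STIMULI, s.ravel()),
                "response": np.take(RESPONSES, r.ravel()),
                "rating": k.ravel(),
                "count": self.counts.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RatingCounts":
        required = {"stimulus", "response", "rating", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        k = int(frame["rating"].max())
        counts = np.zeros((2, 2, k), dtype=np.int64)
        stim = _binary_index(frame["stimulus"].to_numpy(), "stimulus")
        resp = _binary_index(frame["response"].to_numpy(), "response")
        rat = frame["rating"].to_numpy(dtype=np.int64)
        np.add.at(counts, (stim, resp, rat - 1), frame["count"].to_numpy(dtype=np.int64))
        return cls(counts)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RatingCounts":
        return cls.from_frame(pd.read_csv(path))


def _binary_index(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.dtype.kind in "iub":
        idx = values.astype(np.int64)
        if ((idx < 0) | (idx > 1)).any():
            raise ValueError(f"integer {name} labels must be 0 or 1")
        return idx
    lookup = {"nonmatch": 0, "match": 1}
    try:
        return np.array([lookup[v] for v in values], dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"unknown {name} label {err.args[0]!r}") from None
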