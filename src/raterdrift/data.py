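"""Long-format ordinal rating data.

A rating record is a score ``u_{jrt}`` in ``1..K`` assigned by rater ``r``
to examinee ``j`` during rating period (time point) ``t``.  All indices are
1-based in user-facing containers and files; internal numerics convert to
0-based arrays where convenient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CSV_COLUMNS = ("examinee", "rater", "time", "score")


class InvalidParameterError(ValueError):
    """A parameter value lies outside the model's support."""


class DimensionMismatchError(ValueError):
    """Array shapes are inconsistent with the declared J, R, T or K."""


@dataclass(frozen=True)
class RatingDataset:
    """Collection of ordinal ratings indexed by (examinee, rater, time).

    Parameters
    ----------
    examinee, rater, time, score
        Parallel 1-based integer arrays, one entry per observed rating.
    J, R, T, K
        Number of examinees, raters, time points and score categories.
    """

    examinee: np.ndarray
    rater: np.ndarray
    time: np.ndarray
    score: np.ndarray
    J: int
    R: int
    T: int
    K: int

    def __post_init__(self):
        for name in ("examinee", "rater", "time", "score"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            object.__setattr__(self, name, arr)
        n = self.examinee.size
        if not (self.rater.size == self.time.size == self.score.size == n):
            raise DimensionMismatchError("observation columns differ in length")
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if min(self.J, self.R, self.T) < 1:
            raise ValueError("J, R and T must be positive")
        if n:
            self._check_range("examinee", self.examinee, self.J)
            self._check_range("rater", self.rater, self.R)
            self._check_range("time", self.time, self.T)
            self._check_range("score", self.score, self.K)
            triples = np.stack([self.examinee, self.rater, self.time], axis=1)
            if np.unique(triples, axis=0).shape[0] != n:
                raise ValueError("duplicate (examinee, rater, time) triple")

    @staticmethod
    def _check_range(name: str, arr: np.ndarray, upper: int) -> None:
        if arr.min() < 1 or arr.max() > upper:
            raise ValueError(
                f"{name} index out of range 1..{upper}: "
                f"saw [{arr.min()}, {arr.max()}]"
            )

    @property
    def n_obs(self) -> int:
        return int(self.examinee.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "examinee": self.examinee,
                "rater": self.rater,
                "time": self.time,
                "score": self.score,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, J=None, R=None, T=None, K=None) -> "RatingDataset":
        missing = set(CSV_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        e = frame["examinee"].to_numpy(dtype=np.int64)
        r = frame["rater"].to_numpy(dtype=np.int64)
        t = frame["time"].to_numpy(dtype=np.int64)
        s = frame["score"].to_numpy(dtype=np.int64)
        return cls(
            e, r, t, s,
            J=int(J if J is not None else e.max(initial=1)),
            R=int(R if R is not None else r.max(initial=1)),
            T=int(T if T is not None else t.max(initial=1)),
            K=int(K if K is not None else s.max(initial=2)),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, J=None, R=None, T=None, K=None) -> "RatingDataset":
        # strict: non-integer or out-of-range values raise, nothing is clamped
        frame = pd.read_csv(path, dtype={c: np.int64 for c in CSV_COLUMNS})
        return cls.from_frame(frame, J=J, R=R, T=T, K=K)
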