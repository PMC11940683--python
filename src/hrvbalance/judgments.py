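"""Jury judgment container shared by the generator and the statistics layer."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

#: Fixed rating dimension order used throughout.
DIMENSIONS = (
    "Interest",
    "Agreement",
    "Engagement",
    "Authoritativeness",
    "Learning",
    "Clarity",
)

LIKERT_MIN, LIKERT_MAX = 1.0, 5.0


@dataclass(frozen=True)
class JudgmentMatrix:
    """Raters x communicators x 6 dimensions of 1-5 ratings."""

    ratings: np.ndarray  # shape (n_raters, n_communicators, 6)

    def __post_init__(self):
        r = np.asarray(self.ratings, dtype=float)
        object.__setattr__(self, "ratings", r)
        if r.ndim != 3 or r.shape[2] != len(DIMENSIONS):
            raise InvalidInputError(
                f"ratings must be (raters, communicators, {len(DIMENSIONS)}), got {r.shape}"
            )
        if np.any(~np.isfinite(r)) or r.min() < LIKERT_MIN - 1e-9 or r.max() > LIKERT_MAX + 1e-9:
            raise InvalidInputError("ratings must be finite and within [1, 5]")

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_communicators(self) -> int:
        return self.ratings.shape[1]

    def communicator_means(self) -> pd.DataFrame:
        """Mean rating per communicator x dimension (the PCA/clustering input)."""
        m = self.ratings.mean(axis=0)
        return pd.DataFrame(m, columns=list(DIMENSIONS)).rename_axis("communicator")

    def to_frame(self) -> pd.DataFrame:
        """Long format: rater, communicator, dimension, score."""
        R, C, D = self.ratings.shape
        idx = pd.MultiIndex.from_product(
            [range(R), range(C), DIMENSIONS], names=["rater", "communicator", "dimension"]
        )
        return pd.DataFrame({"score": self.ratings.reshape(-1)}, index=idx).reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "JudgmentMatrix":
        piv = df.pivot_table(
            index="rater", columns=["communicator", "dimension"], values="score"
        )
        raters = piv.index.to_numpy()
        comms = sorted(df["communicator"].unique())
        arr = np.empty((len(raters), len(comms), len(DIMENSIONS)))
        for ci, c in enumerate(comms):
            for di, d in enumerate(DIMENSIONS):
                arr[:, ci, di] = piv[(c, d)].to_numpy()
        if np.any(~np.isfinite(arr)):
            raise InvalidInputError("judgment table has missing rater x communicator cells")
        return cls(ratings=arr)
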