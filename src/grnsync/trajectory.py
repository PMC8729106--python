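"""Time-indexed species abundances produced by any simulation engine."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Species abundances on a uniform time grid.

    ``abundances`` has shape (n_species, n_times); ``warnings`` collects
    (time, element, criterion) records emitted by step-size checks.
    """

    times: np.ndarray
    species: list[str]
    abundances: np.ndarray
    warnings: list[tuple[float, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.species), self.times.size):
            raise ValueError("abundances must have shape (n_species, n_times)")

    def series(self, name: str) -> np.ndarray:
        return self.abundances[self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.abundances.T, columns=self.species)
        df.insert(0, "time_s", self.times)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_warnings(self, path) -> None:
        with open(path, "w") as fh:
            for t, element, criterion in self.warnings:
                fh.write(f"{t:.6g}\t{element}\t{criterion}\n")

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        species = [c for c in df.columns if c != "time_s"]
        return cls(
            times=df["time_s"].to_numpy(),
            species=species,
            abundances=df[species].to_numpy().T,
        )
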