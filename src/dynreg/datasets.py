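"""Replicated time-course expression data: container and TSV round-trip.

The central object is :class:`ExpressionDataset`, a genes x samples matrix of
log2 expression with per-sample annotations (time in hours, arm, replicate).
The layout mirrors a two-arm perturbation time course: at each time point a
treated arm and a vehicle-control arm, each with a small number of replicates.

Sample ids encode their annotation as ``t{time}_{condition}_r{replicate}``
(e.g. ``t4_treated_r1``) so a TSV written by this module is self-describing.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd

TREATED = "treated"
CONTROL = "control"

_SAMPLE_RE = re.compile(r"^t(?P<time>\d+(?:\.\d+)?)_(?P<cond>treated|control)_r(?P<rep>\d+)$")


def make_sample_id(time_hours: float, condition: str, replicate: int) -> str:
    t = int(time_hours) if float(time_hours).is_integer() else time_hours
    return f"t{t}_{condition}_r{replicate}"


def parse_sample_id(sample_id: str) -> tuple[float, str, int]:
    m = _SAMPLE_RE.match(sample_id)
    if m is None:
        raise ValueError(
            f"sample id {sample_id!r} does not follow 't<time>_<treated|control>_r<rep>'"
        )
    return float(m.group("time")), m.group("cond"), int(m.group("rep"))


@dataclasses.dataclass
class ExpressionDataset:
    """Genes x samples log2 expression with time/condition/replicate labels.

    Parameters
    ----------
    genes
        Gene identifiers, one per row of ``values``.
    samples
        Unique sample identifiers, one per column of ``values``.
    values
        ``(n_genes, n_samples)`` array of log2 expression, all finite.
    times
        Per-sample time in hours.
    conditions
        Per-sample arm, each ``"treated"`` or ``"control"``.
    replicates
        Per-sample replicate index within its (time, condition) cell.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    times: np.ndarray
    conditions: np.ndarray
    replicates: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.replicates = np.asarray(self.replicates, dtype=int)
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicated gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        bad = set(self.conditions) - {TREATED, CONTROL}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    # ------------------------------------------------------------------ views

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def timepoints(self) -> list[float]:
        """Sorted unique times present in the design."""
        return sorted(set(self.times.tolist()))

    @property
    def stages(self) -> list[float]:
        """Sorted nonzero times: the comparison stages of the time course."""
        return [t for t in self.timepoints if t != 0]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def sample_mask(self, time: float | None = None, condition: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if time is not None:
            mask &= self.times == float(time)
        if condition is not None:
            mask &= self.conditions == condition
        return mask

    def arm_values(self, time: float, condition: str) -> np.ndarray:
        """(n_genes, n_replicates) slice for one (time, condition) cell."""
        mask = self.sample_mask(time, condition)
        if not mask.any():
            raise KeyError(f"no samples at time={time} condition={condition}")
        return self.values[:, mask]

    def mean_profile(self, condition: str, timepoints: list[float] | None = None) -> np.ndarray:
        """Per-gene replicate means over time, shape (n_genes, n_times)."""
        tps = timepoints if timepoints is not None else self.timepoints
        cols = [self.arm_values(t, condition).mean(axis=1) for t in tps]
        return np.column_stack(cols)

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionDataset(
            genes=[self.genes[i] for i in idx],
            samples=self.samples,
            values=self.values[idx, :],
            times=self.times,
            conditions=self.conditions,
            replicates=self.replicates,
        )

    # ------------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionDataset":
        samples = [str(c) for c in df.columns]
        parsed = [parse_sample_id(s) for s in samples]
        return cls(
            genes=[str(g) for g in df.index],
            samples=samples,
            values=df.to_numpy(dtype=float),
            times=np.array([p[0] for p in parsed]),
            conditions=np.array([p[1] for p in parsed], dtype=object),
            replicates=np.array([p[2] for p in parsed]),
        )
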