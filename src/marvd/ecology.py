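"""Coverage-normalised abundance and community-ecology statistics.

Per-contig read coverage (summed per-base depth from mapping) is turned
into a populations × samples abundance matrix, normalised by contig length
and by the total trimmed read bases of each sample so values are comparable
across samples and genome sizes.  A base-10 ``log10(1 + x)`` transform is
available for display; diversity and dissimilarity statistics operate on
the linear matrix.

Alpha diversity per sample: richness ``S`` (populations with nonzero
abundance), Shannon–Wiener ``H' = −Σ p_i ln p_i`` (natural log), and
Pielou's evenness ``J = H'/ln S`` (undefined for S ≤ 1).  Beta diversity:
Bray–Curtis dissimilarity between samples.  Two distance matrices (e.g.
viral community structure at two stations, or viruses vs. host 16S
profiles) are compared with a one-tailed permutation Mantel test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class CoverageTable:
    """Long-format coverage rows plus the per-sample and per-contig metadata.

    ``rows`` holds (sample_id, contig_id, depth_sum) where depth_sum is the
    summed per-base depth (units: bases) of the contig in that sample;
    ``sample_read_bases`` is each sample's total trimmed read bases;
    ``contig_lengths`` is each contig's length in bp.
    """

    rows: pd.DataFrame
    sample_read_bases: dict[str, float]
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        required = {"sample_id", "contig_id", "depth_sum"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"coverage rows need columns {sorted(required)}")
        if (self.rows["depth_sum"] < 0).any():
            raise ValueError("negative depth_sum")
        if self.rows.duplicated(subset=["sample_id", "contig_id"]).any():
            raise ValueError("duplicate (sample, contig) coverage rows")

    @classmethod
    def from_frames(cls, coverage: pd.DataFrame, lengths: pd.DataFrame,
                    samples: pd.DataFrame) -> "CoverageTable":
        """Assemble from the three TSV-shaped frames the CLI reads."""
        return cls(
            rows=coverage,
            sample_read_bases=dict(zip(samples["sample_id"], samples["read_bases"].astype(float))),
            contig_lengths=dict(zip(lengths["contig_id"], lengths["length"].astype(int))),
        )


@dataclass(frozen=True)
class AbundanceMatrix:
    """Populations × samples abundance with its transform tag."""

    values: pd.DataFrame  # index = contig/population ids, columns = sample ids
    transform: str = "linear"  # "linear" | "log10"

    def __post_init__(self) -> None:
        if self.transform not in ("linear", "log10"):
            raise ValueError("transform must be 'linear' or 'log10'")
        if self.transform == "linear" and (self.values.values < 0).any():
            raise ValueError("linear abundances must be non-negative")

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.values[sample_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric distance matrix with zero diagonal."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape/label mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def normalize_abundance(
    cov: CoverageTable, scale: float = 1e9, log: bool = False
) -> AbundanceMatrix:
    """Normalise coverage by contig length and sample sequencing effort.

    linear value = (depth_sum / contig_length) / sample_read_bases × scale —
    i.e. mean per-base depth per sequenced base, rescaled by ``scale`` to a
    readable magnitude.  With ``log=True`` entries become ``log10(1 + x)``
    so absent populations map to exactly 0.  Missing (sample, contig) pairs
    are zero.
    """
    rows = cov.rows
    for contig_id in rows["contig_id"].unique():
        length = cov.contig_lengths.get(contig_id)
        if length is None or length <= 0:
            raise ValueError(f"missing or zero length for contig {contig_id!r}")
    for sample_id in rows["sample_id"].unique():
        bases = cov.sample_read_bases.get(sample_id)
        if bases is None or bases <= 0:
            raise ValueError(f"missing or zero read-base total for sample {sample_id!r}")

    lengths = rows["contig_id"].map(cov.contig_lengths).astype(float)
    bases = rows["sample_id"].map(cov.sample_read_bases).astype(float)
    linear = rows["depth_sum"].astype(float) / lengths / bases * scale
    wide = (
        pd.DataFrame({"contig_id": rows["contig_id"], "sample_id": rows["sample_id"],
                      "value": linear})
        .pivot(index="contig_id", columns="sample_id", values="value")
        .reindex(index=sorted(cov.contig_lengths), columns=sorted(cov.sample_read_bases))
        .fillna(0.0)
    )
    wide.index.name = "contig_id"
    wide.columns.name = "sample_id"
    if log:
        return AbundanceMatrix(values=np.log10(1.0 + wide), transform="log10")
    return AbundanceMatrix(values=wide, transform="linear")


@dataclass(frozen=True)
class AlphaDiversity:
    """Richness, Shannon–Wiener H' (nats by default) and Pielou's J."""

    richness: int
    shannon: float
    pielou: float | None  # None when S <= 1 (evenness undefined)


def alpha_diversity(abundances: Sequence[float] | np.ndarray,
                    base: float = math.e) -> AlphaDiversity:
    """Alpha diversity of one sample's linear abundance vector.

    Proportions are taken over the nonzero entries.  ``H' = −Σ p_i log p_i``
    in the requested log base (natural log by default); ``J = H'/log S``.
    An all-zero vector gives richness 0, H' 0 and undefined evenness.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    nz = x[x > 0]
    richness = int(nz.size)
    if richness == 0:
        return AlphaDiversity(richness=0, shannon=0.0, pielou=None)
    p = nz / nz.sum()
    p = p[p > 0]  # guard against underflow of extreme abundance ratios
    shannon = float(-(p * (np.log(p) / math.log(base))).sum())
    if richness == 1:
        return AlphaDiversity(richness=1, shannon=0.0, pielou=None)
    pielou = shannon / (math.log(richness) / math.log(base))
    return AlphaDiversity(richness=richness, shannon=shannon, pielou=float(pielou))


def alpha_diversity_table(matrix: AbundanceMatrix, base: float = math.e) -> pd.DataFrame:
    """Per-sample alpha-diversity summary of an abundance matrix."""
    if matrix.transform != "linear":
        raise ValueError("alpha diversity is computed on the linear matrix")
    rows = []
    for sample_id in matrix.values.columns:
        d = alpha_diversity(matrix.sample_vector(sample_id), base=base)
        rows.append({"sample_id": sample_id, "richness": d.richness,
                     "shannon": d.shannon,
                     "pielou": math.nan if d.pielou is None else d.pielou})
    return pd.DataFrame(rows)


def bray_curtis(matrix: AbundanceMatrix) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between samples of a linear abundance matrix.

    d(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i), with d = 0 by convention when
    both samples are empty.
    """
    if matrix.transform != "linear":
        raise ValueError("Bray-Curtis requires the linear (untransformed) matrix")
    data = matrix.values.to_numpy(dtype=float).T  # samples × populations
    with np.errstate(invalid="ignore"):
        condensed = pdist(data, metric="braycurtis")
    condensed = np.nan_to_num(condensed, nan=0.0)  # 0/0 -> 0
    return DistanceMatrix(values=squareform(condensed),
                          labels=tuple(matrix.values.columns))


def _pearson_upper(d1: np.ndarray, d2: np.ndarray, iu) -> float:
    x = d1[iu]
    y = d2[iu]
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        raise ValueError("zero variance in distance matrix upper triangle")
    return float((x * y).sum() / denom)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-tailed permutation Mantel test between two distance matrices.

    The statistic is the Pearson correlation of the upper-triangle entries.
    The p-value permutes one matrix's row/column order with the seeded
    generator: p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm), so p ∈ (0, 1].
    """
    if d1.labels != d2.labels:
        raise ValueError(
            f"distance matrix labels differ: {d1.labels} vs {d2.labels}"
        )
    n = len(d1.labels)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 samples")
    iu = np.triu_indices(n, k=1)
    r_obs = _pearson_upper(d1.values, d2.values, iu)

    rng = np.random.default_rng(seed)
    count = 0
    m2 = d2.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _pearson_upper(d1.values, m2[np.ix_(perm, perm)], iu)
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p
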