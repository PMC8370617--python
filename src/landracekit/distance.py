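"""Normalized Hamming (allele-sharing) distances between multilocus genotypes.

For diploid dosages the distance between samples i and j is

    d(i, j) = sum_l |g_il - g_jl| / (2 * n_ij)

summed over loci called in *both* samples (pairwise-complete deletion),
where ``n_ij`` is the count of such loci.  A heterozygote/homozygote
mismatch contributes 1 allele difference, opposite homozygotes contribute 2,
so d is the per-allele mismatch proportion and lies in [0, 1].

Replicate pairs (re-genotyped or re-collected plants of a known clone) give
an empirical scale for genotyping noise; their within-group distances feed
threshold calibration in :mod:`landracekit.clones`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import DistanceMatrix, GenotypeMatrix, SampleMetadata


def hamming_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs normalized Hamming distance from an allele-dosage matrix.

    Pairs sharing no called locus get a NaN (undefined) entry.  The
    computation decomposes |g_i - g_j| over dosage-state indicators so the
    whole matrix reduces to a handful of matrix products; sums of indicator
    products are exact in float64.
    """
    if G.n_samples < 2 or G.n_loci < 1:
        raise ValidationError("need at least 2 samples and 1 locus")
    X = G.dosage
    called = ~np.isnan(X)
    I0 = ((X == 0.0) & called).astype(np.float64)
    I1 = ((X == 1.0) & called).astype(np.float64)
    I2 = ((X == 2.0) & called).astype(np.float64)
    # weight 1: het vs either homozygote; weight 2: opposite homozygotes
    num = I0 @ I1.T + I1 @ I0.T + I1 @ I2.T + I2 @ I1.T + 2.0 * (I0 @ I2.T + I2 @ I0.T)
    n_shared = called.astype(np.float64) @ called.T.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / (2.0 * n_shared)
    d[n_shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(G.sample_ids), d)


@dataclass
class ReplicateDistances:
    """Within-group distances for all replicate pairs, with summaries."""

    pairs: pd.DataFrame  # sample_a, sample_b, replicate_group, replicate_type, distance

    @property
    def distances(self) -> list[float]:
        return list(self.pairs["distance"])

    def summary(self) -> dict:
        out: dict = {"pooled": _summ(self.pairs["distance"])}
        for typ, rows in self.pairs.groupby("replicate_type"):
            out[str(typ)] = _summ(rows["distance"])
        return out


def _summ(d: pd.Series) -> dict:
    return {"n_pairs": int(len(d)), "mean": float(d.mean()), "max": float(d.max())}


def replicate_pair_distances(D: DistanceMatrix, meta: SampleMetadata) -> ReplicateDistances:
    """Enumerate all within-replicate-group pairs and their distances.

    Raises :class:`ValidationError` when no group has two members (threshold
    calibration is then impossible) or when a required distance is undefined.
    """
    rows = []
    for grp, info in meta.replicate_groups().items():
        members = [m for m in info["members"] if m in set(D.ids)]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                dist = D.get(a, b)
                if np.isnan(dist):
                    raise ValidationError(f"distance undefined for replicate pair ({a}, {b})")
                rows.append((a, b, grp, info["type"], dist))
    if not rows:
        raise ValidationError("no replicate group with >=2 members: cannot calibrate")
    pairs = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "replicate_group", "replicate_type", "distance"]
    )
    return ReplicateDistances(pairs)
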