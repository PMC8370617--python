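"""Zone-level diversity and differentiation statistics.

Covers the population-genetic summaries of a zoned germplasm collection:

* Shannon's index on clone (multilocus genotype) abundances per zone,
* pairwise Fst between zones — Weir & Cockerham's (1984) theta by default,
  with a Nei Gst-based alternative,
* Nei's (1972) standard genetic distance between zones, and
* an unweighted neighbor-joining tree of zones from any distance matrix.

Fst here treats each administrative zone as a population.  Because the
collection contains clonal duplicates, the natural unit is the unique
landrace: pass a deduplicated genotype set (one representative per clone
per zone) for the headline estimates, or all samples for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .clones import ClonePartition
from .errors import ValidationError
from .io import DistanceMatrix, GenotypeMatrix, SampleMetadata


# ---------------------------------------------------------------------------
# Shannon diversity on clone abundances
# ---------------------------------------------------------------------------


def shannon_index(abundances) -> float:
    """Shannon's H (nats) over clone abundance counts.

    H = -sum p_i ln p_i with p_i the share of each clone; zero counts are
    excluded.  H is 0 for a single clone and ln(k) for k equally frequent
    clones.
    """
    counts = np.asarray(list(abundances), dtype=float)
    if (counts < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("total abundance must be positive")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def zone_clone_abundances(partition: ClonePartition, meta: SampleMetadata) -> dict[str, pd.Series]:
    """Per zone, the number of collection events of each clone group there.

    Replicate re-entries of one collected accession are a single event (see
    :func:`landracekit.clones.collection_entries`).
    """
    from .clones import collection_entries

    zone = meta.table["zone"]
    entries = set(collection_entries(meta))
    out: dict[str, dict[str, int]] = {}
    for g, members in partition.groups.items():
        for s in members:
            if s in entries:
                z = str(zone[s])
                out.setdefault(z, {}).setdefault(g, 0)
                out[z][g] += 1
    return {z: pd.Series(d).sort_index() for z, d in sorted(out.items())}


def shannon_by_zone(partition: ClonePartition, meta: SampleMetadata) -> pd.Series:
    ab = zone_clone_abundances(partition, meta)
    return pd.Series({z: shannon_index(c) for z, c in ab.items()}, name="shannon")


# ---------------------------------------------------------------------------
# allele frequencies per zone
# ---------------------------------------------------------------------------


def _group_arrays(G: GenotypeMatrix, grouping: Mapping[str, str] | pd.Series):
    grouping = pd.Series(dict(grouping)) if not isinstance(grouping, pd.Series) else grouping
    groups: dict[str, np.ndarray] = {}
    index = {s: i for i, s in enumerate(G.sample_ids)}
    for z in sorted(grouping.dropna().unique()):
        members = [s for s in grouping.index[grouping == z] if s in index]
        if members:
            groups[str(z)] = G.dosage[[index[s] for s in members]]
    return groups


def allele_frequencies(
    G: GenotypeMatrix, grouping: Mapping[str, str] | pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alternate-allele frequency and called-sample count per zone x locus.

    Frequencies are NaN (undefined) where a zone has no called sample.
    """
    groups = _group_arrays(G, grouping)
    if not groups:
        raise ValidationError("grouping assigns no samples present in the matrix")
    freq = {}
    ncalled = {}
    for z, X in groups.items():
        called = (~np.isnan(X)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(X, axis=0) / (2.0 * called)
        p[called == 0] = np.nan
        freq[z] = p
        ncalled[z] = called
    fdf = pd.DataFrame(freq, index=G.locus_ids).T
    ndf = pd.DataFrame(ncalled, index=G.locus_ids).T
    return fdf, ndf


# ---------------------------------------------------------------------------
# pairwise Fst
# ---------------------------------------------------------------------------


def _pair_stats(X: np.ndarray):
    """Per-locus called count, allele frequency and observed het fraction."""
    called = (~np.isnan(X)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * called)
        h = np.nansum(X == 1.0, axis=0) / called
    return called, p, h


def _wc84_theta(Xa: np.ndarray, Xb: np.ndarray) -> float:
    """Weir & Cockerham (1984) multilocus theta for two populations.

    Ratio-of-averages estimator: theta = sum(a) / sum(a + b + c) across
    loci, with variance components computed from per-locus sample sizes,
    allele frequencies and observed heterozygote proportions.
    """
    r = 2.0
    na, pa, ha = _pair_stats(Xa)
    nb, pb, hb = _pair_stats(Xb)
    ok = (na >= 1) & (nb >= 1) & (na + nb > 2)
    na, pa, ha, nb, pb, hb = (v[ok] for v in (na, pa, ha, nb, pb, hb))
    nbar = (na + nb) / r
    nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1.0)
    pbar = (na * pa + nb * pb) / (r * nbar)
    s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (na * ha + nb * hb) / (r * nbar)
    inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def _nei_gst(Xa: np.ndarray, Xb: np.ndarray) -> float:
    """Pairwise Gst: 1 - sum(Hs) / sum(Ht) with Hs the mean within-zone
    expected heterozygosity and Ht the total from the mean frequency."""
    na, pa, _ = _pair_stats(Xa)
    nb, pb, _ = _pair_stats(Xb)
    ok = (na >= 1) & (nb >= 1)
    pa, pb = pa[ok], pb[ok]
    hs = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2.0
    pm = (pa + pb) / 2.0
    ht = 2 * pm * (1 - pm)
    if ht.sum() == 0:
        return float("nan")
    return float(1.0 - hs.sum() / ht.sum())


_FST_ESTIMATORS = {"WC84": _wc84_theta, "Nei87": _nei_gst}


def pairwise_fst(
    G: GenotypeMatrix,
    grouping: Mapping[str, str] | pd.Series,
    estimator: str = "WC84",
) -> pd.DataFrame:
    """Pairwise Fst between all zones in ``grouping``.

    Loci with no call in either zone of a pair are skipped.  Each zone needs
    at least two samples; small negative estimates are possible (and
    expected under no differentiation) and are not clipped.
    """
    if estimator not in _FST_ESTIMATORS:
        raise ValueError(f"estimator must be one of {sorted(_FST_ESTIMATORS)}")
    fn = _FST_ESTIMATORS[estimator]
    groups = _group_arrays(G, grouping)
    small = [z for z, X in groups.items() if X.shape[0] < 2]
    if small:
        raise ValidationError(f"zones with fewer than 2 samples: {small}")
    if len(groups) < 2:
        raise ValidationError("need at least 2 zones")
    zones = list(groups)
    out = pd.DataFrame(0.0, index=zones, columns=zones)
    for i, za in enumerate(zones):
        for zb in zones[i + 1 :]:
            v = fn(groups[za], groups[zb])
            out.loc[za, zb] = out.loc[zb, za] = v
    return out


# ---------------------------------------------------------------------------
# Nei's standard genetic distance
# ---------------------------------------------------------------------------


def nei_distance(x, y, max_distance: float = 10.0) -> float:
    """Nei's (1972) standard genetic distance between two frequency vectors.

    For biallelic loci with alternate-allele frequencies x, y:

        J_xy = sum_l [x y + (1-x)(1-y)],  J_x = sum_l [x^2 + (1-x)^2]

    (ratio of sums across loci), I = J_xy / sqrt(J_x J_y), D = -ln I.
    Loci undefined (NaN) in either vector are skipped; D is clamped to
    ``max_distance`` when I underflows toward 0 (fixed opposite alleles).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if not ok.any():
        raise ValidationError("no shared defined loci between the two zones")
    x, y = x[ok], y[ok]
    jxy = float((x * y + (1 - x) * (1 - y)).sum())
    jx = float((x**2 + (1 - x) ** 2).sum())
    jy = float((y**2 + (1 - y) ** 2).sum())
    identity = jxy / np.sqrt(jx * jy)
    if identity <= np.exp(-max_distance):
        warnings.warn(
            f"genetic identity {identity:.3g} at or below clamp; returning {max_distance}",
            stacklevel=2,
        )
        return float(max_distance)
    return float(max(-np.log(identity), 0.0))


def nei_distance_matrix(freqs: pd.DataFrame, max_distance: float = 10.0) -> DistanceMatrix:
    """All-pairs Nei distance from a zones x loci frequency table."""
    zones = list(freqs.index)
    n = len(zones)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(
                freqs.iloc[i].to_numpy(), freqs.iloc[j].to_numpy(), max_distance
            )
    return DistanceMatrix(zones, d, bounded=False)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _fmt_branch(x: float) -> str:
    return f"{max(x, 0.0):.12g}"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Produces an unrooted tree (trifurcating root in the Newick string).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, preserving the joined pair's path length.  On
    tree-additive input the leaf-to-leaf path lengths reproduce the input
    distances exactly (up to float precision).
    """
    n = D.n
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if np.isnan(D.values).any():
        raise ValidationError(f"undefined distances: {D.undefined_pairs()[:5]}")
    d = D.values.copy()
    labels = [_quote(s) for s in D.ids]
    while len(labels) > 3:
        m = len(labels)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(q.argmin()), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        merged = f"({labels[i]}:{_fmt_branch(li)},{labels[j]}:{_fmt_branch(lj)})"
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        labels = [labels[k] for k in keep] + [merged]
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    newick = (
        f"({labels[0]}:{_fmt_branch(la)},{labels[1]}:{_fmt_branch(lb)},"
        f"{labels[2]}:{_fmt_branch(lc)});"
    )
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------


@dataclass
class DiversityReport:
    """Shannon per zone, pairwise Fst, Nei distances and the zone NJ tree."""

    shannon: pd.Series
    fst: pd.DataFrame
    nei: DistanceMatrix
    zone_tree: dendropy.Tree

    def to_dict(self) -> dict:
        return {
            "shannon": {k: float(v) for k, v in self.shannon.items()},
            "fst": {
                f"{a}|{b}": float(self.fst.loc[a, b])
                for i, a in enumerate(self.fst.index)
                for b in self.fst.columns[i + 1 :]
            },
            "nei": {
                f"{a}|{b}": float(self.nei.get(a, b))
                for i, a in enumerate(self.nei.ids)
                for b in self.nei.ids[i + 1 :]
            },
            "zone_tree_newick": self.zone_tree.as_string(schema="newick").strip(),
        }


def unique_landraces_per_zone(
    partition: ClonePartition, meta: SampleMetadata, G: GenotypeMatrix
) -> tuple[GenotypeMatrix, pd.Series]:
    """Deduplicated genotype set: one member per clone group per zone.

    Within each zone, each clone group contributes the member with the
    fewest missing calls (ties by id); a clone spanning zones contributes
    one member to each.  Returns the subset matrix and its zone grouping.
    """
    cats = meta.table["category"]
    zone = meta.table["zone"]
    frac = G.sample_missing_fraction()
    chosen: list[str] = []
    zones: list[str] = []
    for g, members in partition.groups.items():
        coll = [s for s in members if cats.get(s) == "collected" and s in set(G.sample_ids)]
        by_zone: dict[str, list[str]] = {}
        for s in coll:
            by_zone.setdefault(str(zone[s]), []).append(s)
        for z, ms in sorted(by_zone.items()):
            best = min(ms, key=lambda m: (float(frac[m]), m))
            chosen.append(best)
            zones.append(z)
    sub = G.subset(samples=chosen)
    return sub, pd.Series(zones, index=chosen, name="zone")


def diversity_report(
    G: GenotypeMatrix,
    partition: ClonePartition,
    meta: SampleMetadata,
    estimator: str = "WC84",
    deduplicate: bool = True,
) -> DiversityReport:
    """Full zone-level diversity report.

    ``deduplicate`` (default) computes Fst/Nei on unique landraces per zone
    (one representative per clone per zone); otherwise on all samples.
    """
    shannon = shannon_by_zone(partition, meta)
    if deduplicate:
        Gz, grouping = unique_landraces_per_zone(partition, meta, G)
    else:
        coll = [s for s in meta.collected_ids if s in set(G.sample_ids)]
        Gz = G.subset(samples=coll)
        grouping = meta.zone_of(coll)
    fst = pairwise_fst(Gz, grouping, estimator=estimator)
    freqs, _ = allele_frequencies(Gz, grouping)
    nei = nei_distance_matrix(freqs)
    tree = neighbor_joining(nei)
    return DiversityReport(shannon=shannon, fst=fst, nei=nei, zone_tree=tree)
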