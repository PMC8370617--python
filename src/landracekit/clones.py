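"""Clone calling: replicate-calibrated duplicate threshold, single-linkage
clone groups, representative selection, reference matching and zone-sharing
accounting.

The deduplication logic is the heart of a germplasm fingerprinting study:
two samples are the same clone when their genetic distance falls below a
threshold calibrated on known replicate pairs, and clone groups are the
connected components of the resulting "duplicate" graph (single linkage, so
identity is transitive).  One representative per group defines the set of
unique landraces; groups are then cross-referenced against reference panels
and summarized per administrative zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ValidationError
from .io import DistanceMatrix, GenotypeMatrix, SampleMetadata, ZONES


def calibrate_threshold(rep_distances, granularity: float = 0.001) -> float:
    """Duplicate threshold from replicate distances.

    Returns the smallest integer multiple of ``granularity`` strictly greater
    than the maximum replicate distance, so every known replicate pair
    satisfies d < threshold (e.g. a replicate maximum of 0.02112 yields a
    cutoff of 0.022 at the default granularity).
    """
    rep_distances = list(rep_distances)
    if not rep_distances:
        raise ValidationError("empty replicate distance list")
    mx = max(rep_distances)
    if mx < 0 or any(np.isnan(rep_distances)):
        raise ValidationError("replicate distances must be defined and non-negative")
    k = math.floor(round(mx / granularity, 9)) + 1
    return k * granularity


@dataclass
class ClonePartition:
    """A partition of samples into clone groups below a distance threshold."""

    threshold: float
    groups: dict[str, tuple[str, ...]]  # group id -> sorted member ids
    representative: dict[str, str]  # group id -> representative sample
    sample_to_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_to_group:
            self.sample_to_group = {
                s: g for g, members in self.groups.items() for s in members
            }
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for g, members in self.groups.items():
            if not members:
                raise ValidationError(f"empty clone group {g}")
            overlap = seen.intersection(members)
            if overlap:
                raise ValidationError(f"groups are not disjoint: {sorted(overlap)[:5]}")
            seen.update(members)
            rep = self.representative.get(g)
            if rep not in members:
                raise ValidationError(f"representative {rep!r} not in group {g}")
        if seen != set(self.sample_to_group):
            raise ValidationError("sample_to_group does not cover exactly the group members")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.sample_to_group)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, sample_id: str) -> str:
        return self.sample_to_group[sample_id]

    def labels(self) -> pd.Series:
        """Group label per sample (index sorted by sample id)."""
        return pd.Series({s: g for s, g in self.sample_to_group.items()}).sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.groups):
            for s in self.groups[g]:
                rows.append((s, g, self.representative[g], s == self.representative[g]))
        return pd.DataFrame(
            rows, columns=["sample_id", "group", "representative", "is_representative"]
        )


def select_representative(group, G: GenotypeMatrix | None = None) -> str:
    """Group member with the fewest missing calls; ties break to the
    lexicographically smallest sample id."""
    members = sorted(group)
    if not members:
        raise ValidationError("empty group")
    if G is None:
        return members[0]
    frac = G.sample_missing_fraction()
    missing = {m: float(frac.get(m, np.inf)) for m in members}
    return min(members, key=lambda m: (missing[m], m))


def call_clones(
    D: DistanceMatrix, threshold: float, G: GenotypeMatrix | None = None
) -> ClonePartition:
    """Partition samples into clones: connected components of the graph with
    an edge wherever d(i, j) < threshold (single linkage).

    Raises if any off-diagonal distance is undefined, listing the pair.
    """
    nan_pairs = D.undefined_pairs()
    if nan_pairs:
        raise ValidationError(f"undefined distances for pairs: {nan_pairs[:5]}")
    adj = D.values < threshold
    np.fill_diagonal(adj, False)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    members_by_comp: dict[int, list[str]] = {}
    for sid, c in zip(D.ids, comp):
        members_by_comp.setdefault(int(c), []).append(sid)
    ordered = sorted(members_by_comp.values(), key=lambda ms: min(ms))
    width = max(3, len(str(len(ordered))))
    groups = {f"MLG{k + 1:0{width}d}": tuple(sorted(ms)) for k, ms in enumerate(ordered)}
    reps = {g: select_representative(ms, G) for g, ms in groups.items()}
    return ClonePartition(threshold=threshold, groups=groups, representative=reps)


# ---------------------------------------------------------------------------
# reference matching
# ---------------------------------------------------------------------------


@dataclass
class ReferenceMatches:
    """Identity labels per clone group from the reference panels."""

    table: pd.DataFrame
    # columns: group, identity, n_collected, n_reference_landraces,
    # reference_names, has_breeding_line, breeding_names

    @property
    def n_groups_identified(self) -> int:
        """Groups containing collected samples identified via a reference landrace."""
        t = self.table
        return int(((t["n_reference_landraces"] > 0) & (t["n_collected"] > 0)).sum())

    @property
    def n_landraces_identified(self) -> int:
        """Collected samples that acquired an identity through a reference."""
        t = self.table
        m = (t["n_reference_landraces"] > 0) & (t["n_collected"] > 0)
        return int(t.loc[m, "n_collected"].sum())

    def synonym_groups(self) -> pd.DataFrame:
        """Groups merging two or more distinct reference landraces."""
        return self.table[self.table["n_reference_landraces"] >= 2]

    def breeding_matched_collected(self, partition: ClonePartition, meta: SampleMetadata) -> list[str]:
        """Collected samples identical to a reference breeding line (flagged
        for exclusion from landrace uniqueness accounting)."""
        cats = meta.table["category"]
        out = []
        for g in self.table.loc[self.table["has_breeding_line"], "group"]:
            for s in partition.groups[g]:
                if cats.get(s) == "collected":
                    out.append(s)
        return sorted(out)


def match_references(partition: ClonePartition, meta: SampleMetadata) -> ReferenceMatches:
    """Label clone groups by the reference samples they contain.

    A group is "identified" iff it contains at least one reference landrace;
    groups with two or more distinct references are reference synonym sets;
    groups joining collected samples to a breeding line are flagged.
    """
    cats = meta.table["category"]
    names = meta.table["given_name"]
    rows = []
    for g in sorted(partition.groups):
        members = partition.groups[g]
        refs = [s for s in members if cats.get(s) == "reference_landrace"]
        breeding = [s for s in members if cats.get(s) == "reference_breeding"]
        collected = [s for s in members if cats.get(s) == "collected"]
        ref_names = sorted({str(names.get(s, s)) for s in refs})
        brd_names = sorted({str(names.get(s, s)) for s in breeding})
        identity = "/".join(ref_names) if ref_names else ""
        rows.append(
            (g, identity, len(collected), len(ref_names), ref_names, bool(breeding), brd_names)
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "group",
            "identity",
            "n_collected",
            "n_reference_landraces",
            "reference_names",
            "has_breeding_line",
            "breeding_names",
        ],
    )
    return ReferenceMatches(table)


# ---------------------------------------------------------------------------
# zone-sharing accounting
# ---------------------------------------------------------------------------


def collection_entries(meta: SampleMetadata) -> list[str]:
    """Collected samples collapsed to one entry per replicate group.

    Replicate re-entries of a collected landrace (re-genotyped or
    re-collected material of the same accession) are one collection event;
    zone accounting and abundance counts should not inflate by them.
    """
    t = meta.table
    collected = t[t["category"] == "collected"]
    keep: list[str] = []
    seen_groups: set[str] = set()
    for sid in collected.index:
        grp = collected.loc[sid, "replicate_group"]
        if pd.isna(grp):
            keep.append(sid)
        elif grp not in seen_groups:
            seen_groups.add(grp)
            keep.append(min(collected.index[collected["replicate_group"] == grp]))
    return keep


@dataclass
class ZoneSummary:
    """Per-zone unique-landrace accounting.

    A unique landrace in a zone is any clone group with at least one
    collected member there; a landrace found in several zones counts once in
    each, so per-zone unique counts sum to more than the global count.
    """

    per_zone: pd.DataFrame
    n_unique_excl_references: int
    n_unique_incl_references: int
    n_collected_more_than_once: int  # distinct clones with >= 2 collection events
    excluded_breeding_matches: list[str]

    def check(self) -> None:
        t = self.per_zone
        assert (t["n_collected_once"] + t["n_collected_more_than_once"] == t["n_unique"]).all()
        assert (t["n_unique"] <= t["n_entries"]).all()


def zone_summary(
    partition: ClonePartition,
    meta: SampleMetadata,
    exclude_breeding_matches: bool = True,
) -> ZoneSummary:
    """Count entries, unique landraces and cross-zone sharing per zone.

    Collected samples identical to a reference breeding line are (by
    default) removed before uniqueness accounting, mirroring how a
    mislabeled improved variety is struck from a landrace list.
    """
    cats = meta.table["category"]
    zone = meta.table["zone"]
    matches = match_references(partition, meta)
    excluded = (
        set(matches.breeding_matched_collected(partition, meta))
        if exclude_breeding_matches
        else set()
    )
    entry_ids = [s for s in collection_entries(meta) if s not in excluded]
    entry_set = set(entry_ids)

    # per clone group: collection entries (after exclusion), their zones
    g_collected: dict[str, list[str]] = {}
    g_zones: dict[str, set[str]] = {}
    for g, members in partition.groups.items():
        coll = [s for s in members if s in entry_set]
        if coll:
            g_collected[g] = coll
            g_zones[g] = {str(zone[s]) for s in coll}

    zones_present = [z for z in ZONES if (zone == z).any()]
    rows = []
    for z in zones_present:
        entries = [s for s in entry_ids if zone[s] == z]
        groups_here = [g for g, zs in g_zones.items() if z in zs]
        once = sum(1 for g in groups_here if len(g_collected[g]) == 1)
        multi = len(groups_here) - once
        shared = sum(1 for g in groups_here if len(g_zones[g]) >= 2)
        pct = 100.0 * shared / len(groups_here) if groups_here else 0.0
        rows.append((z, len(entries), multi, once, len(groups_here), shared, pct))
    per_zone = pd.DataFrame(
        rows,
        columns=[
            "zone",
            "n_entries",
            "n_collected_more_than_once",
            "n_collected_once",
            "n_unique",
            "n_shared_across_zones",
            "pct_shared",
        ],
    ).set_index("zone")

    n_excl = len(g_collected)
    ref_only = 0
    for g, members in partition.groups.items():
        if g in g_collected:
            continue
        if any(cats.get(s) == "reference_landrace" for s in members) and not any(
            cats.get(s) == "reference_breeding" for s in members
        ):
            ref_only += 1
    summary = ZoneSummary(
        per_zone=per_zone,
        n_unique_excl_references=n_excl,
        n_unique_incl_references=n_excl + ref_only,
        n_collected_more_than_once=sum(1 for g in g_collected if len(g_collected[g]) >= 2),
        excluded_breeding_matches=sorted(excluded),
    )
    summary.check()
    return summary


# ---------------------------------------------------------------------------
# partition IO
# ---------------------------------------------------------------------------


def write_partition(partition: ClonePartition, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#threshold\t{partition.threshold!r}\n")
        partition.to_frame().to_csv(fh, sep="\t", index=False)


def read_partition(path) -> ClonePartition:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#threshold\t"):
            raise ValidationError(f"{path}: missing #threshold header line")
        threshold = float(first.split("\t", 1)[1])
        t = pd.read_csv(fh, sep="\t", dtype={"sample_id": str, "group": str})
    groups: dict[str, tuple[str, ...]] = {}
    reps: dict[str, str] = {}
    for g, rows in t.groupby("group"):
        groups[str(g)] = tuple(sorted(rows["sample_id"].astype(str)))
        reps[str(g)] = str(rows["representative"].iloc[0])
    return ClonePartition(threshold=threshold, groups=groups, representative=reps)
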