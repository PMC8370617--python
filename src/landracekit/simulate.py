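"""Synthetic genotype, metadata and survey generator with known truth.

The generator emulates the statistical structure of a zoned, clonally
propagated germplasm collection:

* zone allele frequencies follow the Balding-Nichols model — for ancestral
  frequency p and differentiation F, each zone draws
  ``p_z ~ Beta(p (1-F)/F, (1-p)(1-F)/F)``, giving E[p_z] = p and
  Var(p_z) = F p (1-p);
* founder clones are Binomial(2, p_z) multilocus genotypes; collected
  samples are clonal copies of founders, some shared across zones;
* every observed copy passes through a genotyping-error channel:
  heterozygotes are miscalled to either homozygote with probability
  ``het_miscall_rate`` (the dominant artifact of low read depth), and calls
  go missing at ``missing_rate``;
* replicate structure mirrors a real fingerprinting design: biological
  replicate groups (distinct plants of one clone, extra copies carry
  somatic mutations at ``somatic_mutation_rate`` per locus) and technical
  replicate groups (re-genotyped material; the repeat run carries an
  elevated miscall rate, ``tech_error_factor`` times the base rate, which
  reproduces the empirical pattern that technical-replicate distances
  exceed biological ones);
* survey scores come from a latent Gaussian with a target correlation
  matrix, thresholded into 1-5 at equal-probability cut points, with a
  "0 = don't know" missingness code.

A :class:`TruthTable` records the true clone of every sample so recovery
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .clones import ClonePartition
from .errors import ValidationError
from .io import GenotypeMatrix, PrefixRule, SampleMetadata, ZONES
from .survey import TRAITS

#: The generator's collector-number scheme: same prefixes as the field
#: scheme, with wide numeric ranges so any zone size fits.
SYNTHETIC_PREFIX_MAP: tuple[PrefixRule, ...] = (
    PrefixRule("EPM", "Central"),
    PrefixRule("KS", "Coastal", 1, 499),
    PrefixRule("KSF", "Lake", 1, 499),
    PrefixRule("KSF", "Western", 500, 999),
    PrefixRule("Horti", "Northern"),
    PrefixRule("BKP", "SouthernHighlands"),
    PrefixRule("SMS", "Zanzibar"),
)

_ZONE_PREFIX = {
    "Central": ("EPM", 1),
    "Coastal": ("KS", 1),
    "Lake": ("KSF", 1),
    "Western": ("KSF", 500),
    "Northern": ("Horti", 1),
    "SouthernHighlands": ("BKP", 1),
    "Zanzibar": ("SMS", 1),
}

_ZONE_CAPACITY = {"Coastal": 499, "Lake": 499, "Western": 500}

#: Proportion of respondents citing fresh roots (vs flour) as the primary
#: use, per zone.
FRESH_PRIMARY_BY_ZONE = {
    "Lake": 0.53,
    "Northern": 0.90,
    "Coastal": 0.91,
    "Zanzibar": 0.96,
    "SouthernHighlands": 0.34,
    "Western": 0.46,
    "Central": 0.24,
}

_ZONE_WEIGHTS = {
    "Central": 79,
    "Coastal": 53,
    "Lake": 62,
    "Northern": 69,
    "SouthernHighlands": 81,
    "Western": 30,
    "Zanzibar": 53,
}


def default_trait_correlation() -> pd.DataFrame:
    """Latent correlation targets among the use-quality traits.

    Cooking quality and taste are strongly coupled (sweet landraces cook
    well); market demand correlates moderately with cooking quality, taste
    and yield; processing quality runs slightly against taste (bitter
    varieties process well).  After 5-level thresholding the observed
    cooking-taste correlation lands near 0.82 (the latent 0.92 is chosen to
    offset the ~0.89 discretization attenuation of quintile scores).
    """
    R = pd.DataFrame(np.eye(len(TRAITS)), index=TRAITS, columns=TRAITS)
    pairs = {
        ("cooking_quality", "taste"): 0.92,
        ("cooking_quality", "market_demand"): 0.45,
        ("taste", "market_demand"): 0.40,
        ("yield", "market_demand"): 0.38,
        ("cooking_quality", "yield"): 0.25,
        ("taste", "yield"): 0.22,
        ("cooking_quality", "processing_quality"): -0.10,
        ("taste", "processing_quality"): -0.15,
        ("processing_quality", "market_demand"): 0.10,
        ("processing_quality", "yield"): 0.05,
    }
    for (a, b), v in pairs.items():
        R.loc[a, b] = R.loc[b, a] = v
    return R


@dataclass
class SurveyConfig:
    n_respondents: int = 193
    n_landraces: int = 427
    trait_correlation: pd.DataFrame = field(default_factory=default_trait_correlation)
    dont_know_rate: float = 0.08
    fresh_primary_by_zone: dict = field(default_factory=lambda: dict(FRESH_PRIMARY_BY_ZONE))
    dual_secondary_rate: float = 0.354
    unknown_use_rate: float = 0.04
    tertiary_leaves_rate: float = 0.35

    def validate(self) -> None:
        R = np.asarray(self.trait_correlation, dtype=float)
        if R.shape != (len(TRAITS), len(TRAITS)) or not np.allclose(R, R.T):
            raise ValidationError("trait correlation must be a symmetric traits x traits matrix")
        if np.linalg.eigvalsh(R).min() < -1e-9:
            raise ValidationError("trait correlation matrix is not positive semi-definite")
        for r in (self.dont_know_rate, self.dual_secondary_rate, self.unknown_use_rate):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("survey rates must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Design parameters of the synthetic collection.

    Defaults encode the kind of national collection campaign the generator
    emulates: seven administrative zones; ~28% of clones collected more
    than once; a replicate design of four biological groups and twelve
    technical groups giving 20 calibration pairs; a heterozygote-miscall
    rate of 0.01; somatic divergence of 0.001 per locus between distant
    plants of one clone; 5% missing calls.  The number of loci and clones
    per zone are desk-scale defaults (1000 loci, 10 clones per zone) sized
    so a full pipeline run takes well under a second.
    """

    seed: int = 0
    n_loci: int = 1000
    n_zones: int = 7
    fst: float = 0.05
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    clones_per_zone: int = 10
    copies_per_clone: dict[int, float] = field(
        default_factory=lambda: {1: 0.72, 2: 0.18, 3: 0.07, 4: 0.03}
    )
    shared_clone_fraction: float = 0.07
    third_zone_fraction: float = 0.1
    het_miscall_rate: float = 0.01
    tech_error_factor: float = 2.0
    somatic_mutation_rate: float = 0.001
    missing_rate: float = 0.05
    n_reference_landraces: int = 10
    ref_match_fraction: float = 0.5
    n_reference_synonym_pairs: int = 1
    n_breeding_lines: int = 5
    n_collected_matching_breeding: int = 1
    bio_replicate_group_sizes: tuple[int, ...] = (3, 2, 2, 2)
    tech_replicate_group_sizes: tuple[int, ...] = (2,) * 11 + (3,)
    survey: SurveyConfig = field(default_factory=SurveyConfig)

    def validate(self) -> None:
        for r in (
            self.fst,
            self.shared_clone_fraction,
            self.het_miscall_rate,
            self.somatic_mutation_rate,
            self.missing_rate,
            self.ref_match_fraction,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("rates and fractions must lie in [0, 1]")
        if not 0.0 < self.fst < 1.0:
            raise ValidationError("fst must lie strictly in (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValidationError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_zones < 1 or self.n_zones > len(ZONES):
            raise ValidationError(f"n_zones must be in 1..{len(ZONES)}")
        if abs(sum(self.copies_per_clone.values()) - 1.0) > 1e-9:
            raise ValidationError("copies_per_clone probabilities must sum to 1")
        if any(k < 1 for k in self.copies_per_clone):
            raise ValidationError("copy counts must be >= 1")
        n_bio = len(self.bio_replicate_group_sizes)
        n_tech = len(self.tech_replicate_group_sizes)
        if n_bio and min(self.bio_replicate_group_sizes) < 2:
            raise ValidationError("biological replicate groups need >= 2 members")
        if n_tech and min(self.tech_replicate_group_sizes) < 2:
            raise ValidationError("technical replicate groups need >= 2 members")
        # replicate hosts: bio groups sit on reference landraces except the
        # last (a breeding line); tech groups on 5 references, 4 breeding
        # lines, and collected samples beyond that.
        need_ref = max(0, n_bio - 1) + min(n_tech, 5)
        if need_ref > self.n_reference_landraces:
            raise ValidationError(
                f"replicate design needs {need_ref} reference landraces, "
                f"have {self.n_reference_landraces}"
            )
        need_brd = (1 if n_bio else 0) + min(max(n_tech - 5, 0), 4)
        need_brd = max(need_brd, self.n_collected_matching_breeding)
        if need_brd > self.n_breeding_lines:
            raise ValidationError(
                f"design needs {need_brd} breeding lines, have {self.n_breeding_lines}"
            )
        self.survey.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["survey"]["trait_correlation"] = np.asarray(
            self.survey.trait_correlation, dtype=float
        ).tolist()
        d["copies_per_clone"] = {str(k): v for k, v in self.copies_per_clone.items()}
        return d


@dataclass
class TruthTable:
    """Ground truth of one simulated collection."""

    clone_of: pd.Series  # sample_id -> true clone id
    zone_frequencies: pd.DataFrame  # zones x loci
    ancestral_frequencies: pd.Series
    config: SimulationConfig

    def partition(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for s, c in self.clone_of.items():
            out.setdefault(str(c), []).append(str(s))
        return {c: tuple(sorted(ms)) for c, ms in out.items()}

    def to_dict(self) -> dict:
        return {
            "clone_of": {str(k): str(v) for k, v in self.clone_of.items()},
            "config": self.config.to_dict(),
        }


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def simulate_population(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, SampleMetadata, TruthTable]:
    """Generate genotypes, metadata and truth for one synthetic collection.

    Deterministic under ``cfg.seed``; frequency, design and observation
    noise use separate seed substreams so components can be varied
    independently without perturbing the others.
    """
    cfg.validate()
    L = cfg.n_loci
    zones = list(ZONES[: cfg.n_zones])
    rng_freq = _rng(cfg.seed, 0)
    rng_pop = _rng(cfg.seed, 1)
    rng_obs = _rng(cfg.seed, 2)

    lo, hi = cfg.ancestral_maf_range
    p_anc = rng_freq.uniform(lo, hi, L)
    F = cfg.fst
    zone_freq = {
        z: rng_freq.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F) for z in zones
    }

    # --- founders ---------------------------------------------------------
    founders: list[dict] = []  # genotype, freq (for somatic resampling), home zone

    def new_founder(freq: np.ndarray, zone: str | None) -> int:
        founders.append(
            {"genotype": rng_pop.binomial(2, freq).astype(np.float64), "freq": freq, "zone": zone}
        )
        return len(founders) - 1

    zone_founders: dict[str, list[int]] = {}
    for z in zones:
        zone_founders[z] = [new_founder(zone_freq[z], z) for _ in range(cfg.clones_per_zone)]

    # --- collected copies -------------------------------------------------
    copy_vals = np.array(sorted(cfg.copies_per_clone))
    copy_p = np.array([cfg.copies_per_clone[k] for k in copy_vals], dtype=float)
    placements: list[tuple[int, str]] = []  # (founder_idx, zone) one per collected sample
    for z in zones:
        for f in zone_founders[z]:
            for _ in range(int(rng_pop.choice(copy_vals, p=copy_p))):
                placements.append((f, z))

    total_clones = len(founders)
    n_shared = int(round(cfg.shared_clone_fraction * total_clones))
    if len(zones) >= 2 and n_shared:
        shared = rng_pop.choice(total_clones, size=n_shared, replace=False)
        for f in shared:
            home = founders[f]["zone"]
            others = [z for z in zones if z != home]
            extra = 2 if (len(others) >= 2 and rng_pop.random() < cfg.third_zone_fraction) else 1
            for z in rng_pop.choice(others, size=extra, replace=False):
                placements.append((int(f), str(z)))

    # --- reference panels -------------------------------------------------
    n_ref = cfg.n_reference_landraces
    n_match = int(round(cfg.ref_match_fraction * n_ref))
    ref_founder: list[int] = []
    if n_match:
        if n_match > total_clones:
            raise ValidationError("more matching references than founders")
        matched = rng_pop.choice(total_clones, size=n_match, replace=False)
        ref_founder.extend(int(f) for f in matched)
    k = n_ref - n_match
    for pair in range(min(cfg.n_reference_synonym_pairs, k // 2)):
        z = str(rng_pop.choice(zones))
        f = new_founder(zone_freq[z], z)
        ref_founder.extend([f, f])
        k -= 2
    for _ in range(k):
        z = str(rng_pop.choice(zones))
        ref_founder.append(new_founder(zone_freq[z], z))

    breeding_founder = [new_founder(p_anc, None) for _ in range(cfg.n_breeding_lines)]

    # --- assemble sample table -------------------------------------------
    samples: list[dict] = []

    def add_sample(sid, founder_idx, zone, category, name, grp=None, typ=None, tech_repeat=False, somatic=False):
        samples.append(
            dict(
                sample_id=sid,
                founder=founder_idx,
                zone=zone,
                category=category,
                given_name=name,
                replicate_group=grp,
                replicate_type=typ,
                tech_repeat=tech_repeat,
                somatic=somatic,
            )
        )

    counters = {z: _ZONE_PREFIX[z][1] for z in zones}
    by_zone_order = sorted(range(len(placements)), key=lambda i: (placements[i][1], i))
    name_no = 1
    collected_ids_by_zone: dict[str, list[str]] = {z: [] for z in zones}
    for i in by_zone_order:
        f, z = placements[i]
        prefix, start = _ZONE_PREFIX[z]
        num = counters[z]
        cap = _ZONE_CAPACITY.get(z)
        if cap is not None and num - start + 1 > cap:
            raise ValidationError(f"zone {z} exceeds its collector-number range")
        counters[z] += 1
        sid = f"{prefix}{num}"
        add_sample(sid, f, z, "collected", f"LR{name_no:04d}")
        collected_ids_by_zone[z].append(sid)
        name_no += 1

    if cfg.n_collected_matching_breeding:
        for j in range(cfg.n_collected_matching_breeding):
            z = str(rng_pop.choice(zones))
            prefix, start = _ZONE_PREFIX[z]
            sid = f"{prefix}{counters[z]}"
            counters[z] += 1
            add_sample(sid, breeding_founder[j % len(breeding_founder)], z, "collected", f"LR{name_no:04d}")
            collected_ids_by_zone[z].append(sid)
            name_no += 1

    for r, f in enumerate(ref_founder):
        add_sample(f"REF{r + 1:02d}", f, None, "reference_landrace", f"RefLandrace{r + 1:02d}")
    for b, f in enumerate(breeding_founder):
        add_sample(f"BRD{b + 1:02d}", f, None, "reference_breeding", f"BreedLine{b + 1:02d}")

    # --- replicate groups -------------------------------------------------
    index = {s["sample_id"]: s for s in samples}

    def host_extend(host_id: str, grp: str, typ: str, size: int) -> None:
        host = index[host_id]
        host["replicate_group"], host["replicate_type"] = grp, typ
        for k in range(2, size + 1):
            extra = dict(host)
            if host["zone"] is not None:
                # re-collected/re-genotyped entries of collected landraces are
                # logged under their own collector number in the same zone
                prefix, _ = _ZONE_PREFIX[host["zone"]]
                extra["sample_id"] = f"{prefix}{counters[host['zone']]}"
                counters[host["zone"]] += 1
            else:
                extra["sample_id"] = f"{host_id}_R{k}"
            extra["tech_repeat"] = typ == "technical"
            extra["somatic"] = typ == "biological"
            samples.append(extra)

    n_bio = len(cfg.bio_replicate_group_sizes)
    ref_hosts = iter([f"REF{r + 1:02d}" for r in range(n_ref)])
    brd_hosts = iter([f"BRD{b + 1:02d}" for b in range(cfg.n_breeding_lines)])
    for g, size in enumerate(cfg.bio_replicate_group_sizes, start=1):
        host = next(brd_hosts) if (n_bio and g == n_bio and cfg.n_breeding_lines) else next(ref_hosts)
        host_extend(host, f"BIO{g}", "biological", size)
    all_collected = [s for z in zones for s in collected_ids_by_zone[z]]
    coll_pick = list(rng_pop.choice(all_collected, size=len(all_collected), replace=False))
    for g, size in enumerate(cfg.tech_replicate_group_sizes, start=1):
        if g <= 5:
            host = next(ref_hosts)
        elif g <= 9:
            host = next(brd_hosts)
        else:
            host = coll_pick.pop()
        host_extend(host, f"TECH{g}", "technical", size)

    # --- observation channel ---------------------------------------------
    n = len(samples)
    X = np.empty((n, L))
    for i, s in enumerate(samples):
        X[i] = founders[s["founder"]]["genotype"]
    somatic_rows = [i for i, s in enumerate(samples) if s["somatic"]]
    for i in somatic_rows:
        freq = founders[samples[i]["founder"]]["freq"]
        mut = rng_obs.random(L) < cfg.somatic_mutation_rate
        if mut.any():
            X[i, mut] = rng_obs.binomial(2, freq[mut])
    eps = np.full(n, cfg.het_miscall_rate)
    eps[[i for i, s in enumerate(samples) if s["tech_repeat"]]] *= cfg.tech_error_factor
    mis = (rng_obs.random((n, L)) < eps[:, None]) & (X == 1.0)
    direction = rng_obs.random((n, L)) < 0.5
    X[mis & direction] = 0.0
    X[mis & ~direction] = 2.0
    X[rng_obs.random((n, L)) < cfg.missing_rate] = np.nan

    sample_ids = [s["sample_id"] for s in samples]
    locus_ids = [f"SNP{j + 1:05d}" for j in range(L)]
    G = GenotypeMatrix(sample_ids, locus_ids, X)

    meta_table = pd.DataFrame(
        {
            "given_name": [s["given_name"] for s in samples],
            "zone": [s["zone"] for s in samples],
            "category": [s["category"] for s in samples],
            "replicate_group": [s["replicate_group"] for s in samples],
            "replicate_type": [s["replicate_type"] for s in samples],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta = SampleMetadata(meta_table)

    width = max(4, len(str(len(founders))))
    clone_ids = {f: f"C{f + 1:0{width}d}" for f in range(len(founders))}
    truth = TruthTable(
        clone_of=pd.Series(
            {s["sample_id"]: clone_ids[s["founder"]] for s in samples}, name="clone"
        ),
        zone_frequencies=pd.DataFrame(zone_freq, index=locus_ids).T,
        ancestral_frequencies=pd.Series(p_anc, index=locus_ids, name="p"),
        config=cfg,
    )
    return G, meta, truth


# ---------------------------------------------------------------------------
# survey simulation
# ---------------------------------------------------------------------------


def simulate_survey(cfg: SimulationConfig, meta: SampleMetadata | None = None) -> pd.DataFrame:
    """Generate a key-informant survey table.

    One row per collected landrace (taken from ``meta`` when given, else
    ``cfg.survey.n_landraces`` synthetic rows with zone shares mirroring
    the emulated collection).  Trait scores are a thresholded latent
    Gaussian with the configured correlation; each score is independently
    replaced by the "don't know" code 0.  Uses follow zone-specific
    fresh/flour propensities with a dual-purpose secondary-use rate.
    """
    cfg.validate()
    sc = cfg.survey
    rng = _rng(cfg.seed, 3)
    zones = list(ZONES[: cfg.n_zones])

    if meta is not None:
        ids = meta.collected_ids
        zone_of = [str(meta.table.loc[s, "zone"]) for s in ids]
    else:
        w = np.array([_ZONE_WEIGHTS[z] for z in zones], dtype=float)
        w /= w.sum()
        counts = rng.multinomial(sc.n_landraces, w)
        ids, zone_of = [], []
        k = 1
        for z, c in zip(zones, counts):
            for _ in range(c):
                ids.append(f"LR{k:04d}")
                zone_of.append(z)
                k += 1
    n = len(ids)
    if n == 0:
        raise ValidationError("no collected landraces to survey")

    # trait scores: latent MVN -> equal-probability quintiles 1..5 -> 0s
    R = np.asarray(sc.trait_correlation, dtype=float)
    latent = rng.multivariate_normal(np.zeros(len(TRAITS)), R, size=n, method="cholesky")
    cuts = norm.ppf([0.2, 0.4, 0.6, 0.8])
    scores = np.searchsorted(cuts, latent) + 1
    scores[rng.random(scores.shape) < sc.dont_know_rate] = 0

    # uses
    use_p, use_s, use_t = [], [], []
    for z in zone_of:
        if rng.random() < sc.unknown_use_rate:
            use_p.append(None), use_s.append(None), use_t.append(None)
            continue
        fresh_first = rng.random() < sc.fresh_primary_by_zone.get(z, 0.5)
        primary = "fresh_consumption" if fresh_first else "flour_processing"
        secondary = None
        if rng.random() < sc.dual_secondary_rate:
            secondary = "flour_processing" if fresh_first else "fresh_consumption"
        tertiary = "leaves_consumption" if rng.random() < sc.tertiary_leaves_rate else None
        if secondary is None and tertiary is not None:
            secondary, tertiary = tertiary, None
        use_p.append(primary), use_s.append(secondary), use_t.append(tertiary)

    # respondents: allocated to zones proportionally to landrace counts
    zs = pd.Series(zone_of)
    n_resp = min(sc.n_respondents, n)
    share = (zs.value_counts() / n * n_resp).round().astype(int).clip(lower=1)
    profiles = {}
    rid = 1
    for z, c in share.items():
        for _ in range(int(c)):
            land_band = rng.choice(5, p=[0.135, 0.427, 0.245, 0.177, 0.016])
            land = [
                rng.uniform(0.1, 0.99),
                rng.uniform(1.0, 4.9),
                rng.uniform(5.0, 9.9),
                rng.uniform(10.0, 30.0),
                np.nan,
            ][land_band]
            yrs_band = rng.choice(5, p=[0.25, 0.31, 0.40, 0.02, 0.02])
            yrs = [
                int(rng.integers(1, 5)),
                int(rng.integers(5, 20)),
                int(rng.integers(20, 50)),
                int(rng.integers(50, 61)),
                np.nan,
            ][yrs_band]
            profiles[f"RESP{rid:03d}"] = dict(
                zone=z,
                gender="female" if rng.random() < 0.26 else "male",
                age=int(rng.integers(18, 87)),
                education=str(rng.choice(
                    ["none", "primary", "secondary", "tertiary"], p=[0.22, 0.66, 0.10, 0.02]
                )),
                land_acres=land,
                years_growing=yrs,
                growing_trend=str(rng.choice(
                    ["increase", "stable", "decrease", "unknown"], p=[0.55, 0.20, 0.15, 0.10]
                )),
                seed_source=str(rng.choice(
                    ["own", "own_plus_gift", "gift", "purchase", "other"],
                    p=[0.63, 0.13, 0.20, 0.01, 0.03],
                )),
            )
            rid += 1
    by_zone_resp: dict[str, list[str]] = {}
    for r, prof in profiles.items():
        by_zone_resp.setdefault(prof["zone"], []).append(r)
    resp_of = []
    zcount: dict[str, int] = {}
    for z in zone_of:
        pool = by_zone_resp[z]
        resp_of.append(pool[zcount.get(z, 0) % len(pool)])
        zcount[z] = zcount.get(z, 0) + 1

    table = pd.DataFrame(
        {
            "collector_id": ids,
            "zone": zone_of,
            "respondent_id": resp_of,
            "use_primary": use_p,
            "use_secondary": use_s,
            "use_tertiary": use_t,
        }
    )
    for t, col in zip(TRAITS, scores.T):
        table[t] = col
    for fieldname in (
        "gender",
        "age",
        "education",
        "land_acres",
        "years_growing",
        "growing_trend",
        "seed_source",
    ):
        table[fieldname] = [profiles[r][fieldname] for r in resp_of]
    return table


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    ari: float
    n_false_merges: int  # called groups mixing distinct true clones
    n_false_splits: int  # true clones split across called groups
    n_called_groups: int
    n_true_clones: int

    @property
    def exact(self) -> bool:
        return self.ari == 1.0 and not self.n_false_merges and not self.n_false_splits


def evaluate_recovery(called: ClonePartition, truth: TruthTable) -> RecoveryMetrics:
    """Score a called partition against the simulated truth.

    The partition may cover a subset of the truth (samples dropped by QC);
    samples unknown to the truth are an error.
    """
    from sklearn.metrics import adjusted_rand_score

    pred = called.labels()
    unknown = set(pred.index) - set(truth.clone_of.index)
    if unknown:
        raise ValidationError(f"partition contains samples unknown to truth: {sorted(unknown)[:5]}")
    true = truth.clone_of.loc[pred.index]
    ari = float(adjusted_rand_score(true.to_numpy(), pred.to_numpy()))
    ct = pd.crosstab(true, pred)
    merges = int(((ct > 0).sum(axis=0) > 1).sum())
    splits = int(((ct > 0).sum(axis=1) > 1).sum())
    return RecoveryMetrics(
        ari=ari,
        n_false_merges=merges,
        n_false_splits=splits,
        n_called_groups=called.n_groups,
        n_true_clones=int(true.nunique()),
    )
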