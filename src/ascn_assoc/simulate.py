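"""Synthetic cohort generator: genotypes, ASCN profiles and a truth table.

The generator emulates the output contract of an ASCAT-style caller on a
glioma-like cohort so the full pipeline is testable without external data:

* germline genotypes at one risk variant, drawn under Hardy-Weinberg at a
  given minor-allele frequency (or at fixed group sizes);
* a bimodal ploidy mixture — a diploid-like majority with baseline (1,1)
  and ploidy near 2, and a tetraploid-like subpopulation with baseline
  (2,2) and ploidy near 4 (whole-genome duplicated);
* segment-structured background copy-number changes at a configurable rate;
* planted genotype-conditional events at named loci: whole-region (nA, nB)
  overwrites with probability ``p_risk`` in the risk group and ``p_other``
  otherwise, recorded in a truth table. Planted states are defined on the
  diploid scale and doubled in tetraploid-like samples (a homozygous
  deletion is (0,0) regardless of ploidy).

Defaults mirror the published study conditions: 81 discovery samples with a
~60/21 major-homozygous split, 23% tetraploid-like, and planted EGFR-LOH /
CDKN2A-HD / CDKN2B-HD effects at the published per-group frequencies, on a
reduced genome (chr7, chr9, chrX) with 100 kb probe spacing densified
inside planted loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .model import (
    ASCNProfile,
    EventType,
    GeneRegion,
    Genotype,
    GenotypeTable,
    PloidyClass,
    ProbeManifest,
    RiskVariantSpec,
    normalize_chrom,
)

__all__ = [
    "PlantedLocus",
    "SimConfig",
    "SimResult",
    "simulate_cohort",
    "emit_fixture",
    "load_sim_config",
    "write_sim_config",
    "EVENT_STATES",
]

#: Canonical (nA, nB) planted per event type, on the diploid (post-rescale)
#: scale. Tetraploid-like samples receive the doubled state.
EVENT_STATES: dict[EventType, tuple[float, float]] = {
    EventType.HD: (0, 0),
    EventType.LOH: (0, 1),
    EventType.LOSS: (0, 1),
    EventType.CNNE: (0, 2),
    EventType.ICN: (1, 2),
    EventType.AMP: (4, 4),
    EventType.LOH_ICN: (0, 3),
    EventType.NORMAL: (1, 1),
}

_DEFAULT_BACKGROUND_STATES: tuple[tuple[tuple[float, float], float], ...] = (
    ((0, 1), 0.35),  # hemizygous loss
    ((1, 2), 0.30),  # single-copy gain
    ((0, 2), 0.15),  # copy-neutral LOH
    ((2, 2), 0.10),  # balanced gain
    ((0, 0), 0.05),  # homozygous deletion
    ((4, 4), 0.05),  # amplification
)


@dataclass(frozen=True)
class PlantedLocus:
    """A genotype-conditional somatic event planted across a whole region."""

    name: str
    chrom: str
    start: int
    end: int
    event: EventType
    p_risk: float
    p_other: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not isinstance(self.event, EventType):
            object.__setattr__(self, "event", EventType.from_label(self.event))
        for p in (self.p_risk, self.p_other):
            if not 0.0 <= p <= 1.0:
                raise ValueError("event probabilities must lie in [0, 1]")
        if self.start > self.end:
            raise ValueError(f"locus {self.name}: start > end")

    @property
    def region(self) -> GeneRegion:
        return GeneRegion(self.name, self.chrom, self.start, self.end)


def _default_chrom_lengths() -> dict[str, int]:
    return {"7": 159_000_000, "9": 141_000_000, "X": 155_000_000}


def _default_planted() -> list[PlantedLocus]:
    # per-group frequencies taken from the published discovery counts
    return [
        PlantedLocus("EGFR", "7", 55_054_218, 55_242_525, EventType.LOH, 19 / 60, 2 / 21),
        PlantedLocus("CDKN2A", "9", 21_957_750, 21_965_132, EventType.HD, 35 / 60, 5 / 21),
        PlantedLocus("CDKN2B", "9", 21_992_901, 21_999_312, EventType.HD, 34 / 60, 5 / 21),
    ]


@dataclass
class SimConfig:
    """Study conditions of a simulated cohort.

    Parameters
    ----------
    n_samples
        Cohort size (81, the discovery cohort with a solved ASCN profile).
    chrom_lengths, probe_spacing, probes_per_planted_locus
        Genome model: uniform probe grid per chromosome (bp spacing) with
        extra probes spread evenly inside each planted locus, emulating the
        gene-centric density of genotyping arrays.
    variant_id, variant_chrom, variant_pos, maf, risk_allele_is_major
        The single risk variant conditioning planted events. Genotypes are
        Hardy-Weinberg draws at ``maf`` unless ``fixed_group_sizes`` pins
        (n major-hom, n het+rare-hom) exactly.
    frac_tetraploid
        Probability a sample is tetraploid-like (whole-genome duplicated).
    planted
        Loci carrying genotype-conditional events.
    co_occur
        Correlation knob in [0, 1] linking the first two planted loci: with
        this probability a sample reuses one shared latent uniform for both
        loci (0 = independent planting).
    background_rate_per_mb, background_mean_length, background_states
        Poisson rate (segments per Mb per sample), mean segment length (bp)
        and the (nA, nB)-state mixture of background aberrations, on the
        diploid scale.
    missing_rate
        Per-probe probability that a sample's (nA, nB) is missing.
    sample_prefix
        Prefix of generated sample ids (separate cohorts should use
        different prefixes).
    seed
        Default RNG seed used when none is passed to the generator.
    """

    n_samples: int = 81
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    probe_spacing: int = 100_000
    probes_per_planted_locus: int = 12
    variant_id: str = "rs17172430"
    variant_chrom: str = "7"
    variant_pos: int = 55_090_144
    maf: float = 0.14
    risk_allele_is_major: bool = True
    fixed_group_sizes: tuple[int, int] | None = None
    frac_tetraploid: float = 0.23
    planted: list[PlantedLocus] = field(default_factory=_default_planted)
    co_occur: float = 0.0
    background_rate_per_mb: float = 0.03
    background_mean_length: float = 2_000_000.0
    background_states: tuple = _DEFAULT_BACKGROUND_STATES
    missing_rate: float = 0.01
    sample_prefix: str = "S"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if not 0.0 <= self.frac_tetraploid <= 1.0:
            raise ValueError("frac_tetraploid must lie in [0, 1]")
        if not 0.0 <= self.co_occur <= 1.0:
            raise ValueError("co_occur must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.fixed_group_sizes is not None:
            self.fixed_group_sizes = tuple(self.fixed_group_sizes)
            if sum(self.fixed_group_sizes) != self.n_samples:
                raise ValueError("fixed_group_sizes must sum to n_samples")
        lengths = {normalize_chrom(c): int(l) for c, l in self.chrom_lengths.items()}
        self.chrom_lengths = lengths
        self.planted = [
            p if isinstance(p, PlantedLocus) else PlantedLocus(**p) for p in self.planted
        ]
        for locus in self.planted:
            if locus.chrom not in lengths:
                raise ValueError(f"locus {locus.name} on unknown chromosome {locus.chrom}")
            if locus.end > lengths[locus.chrom]:
                raise ValueError(f"locus {locus.name} extends beyond its chromosome")
        by_chrom: dict[str, list[PlantedLocus]] = {}
        for locus in self.planted:
            for prev in by_chrom.get(locus.chrom, []):
                if locus.start <= prev.end and prev.start <= locus.end:
                    raise ValueError(
                        f"planted loci overlap: {prev.name} and {locus.name}"
                    )
            by_chrom.setdefault(locus.chrom, []).append(locus)

    @property
    def risk_variant(self) -> RiskVariantSpec:
        major, rare = "G", "A"
        return RiskVariantSpec(
            variant_id=self.variant_id,
            chrom=normalize_chrom(self.variant_chrom),
            pos=self.variant_pos,
            gene="synthetic",
            major_allele=major,
            risk_allele=major if self.risk_allele_is_major else rare,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted"] = [
            {
                "name": p.name,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "event": p.event.name,
                "p_risk": p.p_risk,
                "p_other": p.p_other,
            }
            for p in self.planted
        ]
        d["background_states"] = [
            {"nA": s[0], "nB": s[1], "weight": w} for (s, w) in self.background_states
        ]
        if self.fixed_group_sizes is not None:
            d["fixed_group_sizes"] = list(self.fixed_group_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "background_states" in d:
            d["background_states"] = tuple(
                ((float(s["nA"]), float(s["nB"])), float(s["weight"]))
                for s in d["background_states"]
            )
        if d.get("fixed_group_sizes") is not None:
            d["fixed_group_sizes"] = tuple(d["fixed_group_sizes"])
        return cls(**d)


@dataclass
class SimResult:
    """Everything a pipeline run needs, plus ground truth."""

    manifest: ProbeManifest
    genotypes: GenotypeTable
    profiles: list[ASCNProfile]
    truth_loci: pd.DataFrame  # sample_id, locus, planted
    truth_samples: pd.DataFrame  # sample_id, genotype, ploidy_class, ploidy
    variant: RiskVariantSpec
    regions: list[GeneRegion]


def _build_manifest(config: SimConfig) -> ProbeManifest:
    rows = []
    for chrom, length in config.chrom_lengths.items():
        grid = np.arange(config.probe_spacing, length + 1, config.probe_spacing)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": grid}))
    for locus in config.planted:
        dense = np.linspace(
            locus.start, locus.end, config.probes_per_planted_locus, dtype=np.int64
        )
        rows.append(pd.DataFrame({"chrom": locus.chrom, "pos": dense}))
    df = pd.concat(rows, ignore_index=True).drop_duplicates(["chrom", "pos"])
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    df["probe_id"] = [f"p{i:06d}" for i in range(len(df))]
    return ProbeManifest(df)


def _draw_genotypes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Genotype category per sample (Hardy-Weinberg or fixed group sizes)."""
    q = config.maf
    if config.fixed_group_sizes is None:
        minor_count = rng.binomial(2, q, size=config.n_samples)
        cats = np.array(
            [Genotype.MAJOR_HOM.value, Genotype.HET.value, Genotype.RARE_HOM.value]
        )
        return cats[minor_count]
    n_major, n_carrier = config.fixed_group_sizes
    # split carriers het vs rare-hom at the conditional Hardy-Weinberg odds
    p_rare_given_carrier = q * q / (2 * (1 - q) * q + q * q)
    n_rare = rng.binomial(n_carrier, p_rare_given_carrier)
    geno = np.array(
        [Genotype.MAJOR_HOM.value] * n_major
        + [Genotype.RARE_HOM.value] * n_rare
        + [Genotype.HET.value] * (n_carrier - n_rare)
    )
    rng.shuffle(geno)
    return geno


def simulate_cohort(
    config: SimConfig, seed: int | None = None
) -> SimResult:
    """Generate one cohort under the configured study conditions.

    All draws come from a single generator seeded with ``seed`` (default
    ``config.seed``), so runs are bit-reproducible.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    manifest = _build_manifest(config)
    n_probes = manifest.n_probes
    chrom_arr = manifest.chrom
    pos_arr = manifest.pos

    geno = _draw_genotypes(config, rng)
    sample_ids = [f"{config.sample_prefix}{i + 1:04d}" for i in range(config.n_samples)]
    is_major = geno == Genotype.MAJOR_HOM.value
    in_risk = is_major if config.risk_allele_is_major else ~is_major

    locus_probes = {
        locus.name: manifest.probes_in_region(locus.chrom, locus.start, locus.end)
        for locus in config.planted
    }

    chrom_names = list(config.chrom_lengths)
    chrom_len = np.array([config.chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_weights = chrom_len / chrom_len.sum()
    total_mb = chrom_len.sum() / 1e6
    states = [np.array(s, dtype=float) for s, _ in config.background_states]
    weights = np.array([w for _, w in config.background_states], dtype=float)
    weights = weights / weights.sum()

    profiles: list[ASCNProfile] = []
    truth_rows = []
    sample_rows = []
    for i, sid in enumerate(sample_ids):
        tetra = rng.random() < config.frac_tetraploid
        if tetra:
            ploidy = float(np.clip(rng.normal(3.7, 0.3), 2.9, 4.6))
            mult = 2.0
        else:
            ploidy = float(np.clip(rng.normal(2.05, 0.15), 1.7, 2.8))
            mult = 1.0
        n_a = np.full(n_probes, mult)
        n_b = np.full(n_probes, mult)

        # background segments (unstructured somatic noise)
        n_seg = rng.poisson(config.background_rate_per_mb * total_mb)
        for _ in range(n_seg):
            ci = rng.choice(len(chrom_names), p=chrom_weights)
            chrom = chrom_names[ci]
            start = float(rng.uniform(1, chrom_len[ci]))
            length = float(rng.exponential(config.background_mean_length))
            state = states[rng.choice(len(states), p=weights)] * mult
            idx = manifest.probes_in_region(chrom, int(start), int(start + length))
            n_a[idx] = state[0]
            n_b[idx] = state[1]

        # planted genotype-conditional events override background
        u_shared = rng.random()
        for k, locus in enumerate(config.planted):
            p = locus.p_risk if in_risk[i] else locus.p_other
            if k < 2 and config.co_occur > 0 and rng.random() < config.co_occur:
                u = u_shared
            else:
                u = rng.random()
            planted = u < p
            if planted:
                state = np.array(EVENT_STATES[locus.event], dtype=float) * mult
                idx = locus_probes[locus.name]
                n_a[idx] = state[0]
                n_b[idx] = state[1]
            truth_rows.append(
                {"sample_id": sid, "locus": locus.name, "planted": planted}
            )

        if config.missing_rate > 0:
            miss = rng.random(n_probes) < config.missing_rate
            n_a[miss] = np.nan
            n_b[miss] = np.nan

        profiles.append(
            ASCNProfile(sample_id=sid, n_a=n_a, n_b=n_b, ploidy=ploidy)
        )
        sample_rows.append(
            {
                "sample_id": sid,
                "genotype": geno[i],
                "ploidy_class": (
                    PloidyClass.TETRAPLOID_LIKE if tetra else PloidyClass.DIPLOID_LIKE
                ).value,
                "ploidy": ploidy,
            }
        )

    genotypes = GenotypeTable(
        pd.DataFrame({config.variant_id: geno}, index=sample_ids)
    )
    return SimResult(
        manifest=manifest,
        genotypes=genotypes,
        profiles=profiles,
        truth_loci=pd.DataFrame(truth_rows),
        truth_samples=pd.DataFrame(sample_rows),
        variant=config.risk_variant,
        regions=[locus.region for locus in config.planted],
    )


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(data)


def write_sim_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def emit_fixture(config: SimConfig, out_dir, seed: int | None = None) -> dict:
    """Simulate a cohort and write every table in the standard formats.

    Returns a dict of written paths. Identical (config, seed) pairs produce
    byte-identical files.
    """
    from pathlib import Path

    from . import io as aio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    used_seed = config.seed if seed is None else seed
    sim = simulate_cohort(config, seed=used_seed)
    paths = {
        "manifest": out / "manifest.tsv",
        "profiles": out / "profiles.tsv",
        "genotypes": out / "genotypes.tsv",
        "regions": out / "regions.tsv",
        "truth_loci": out / "truth_loci.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "config": out / "sim_config.yaml",
    }
    aio.write_manifest(sim.manifest, paths["manifest"], seed=used_seed)
    aio.write_profiles(sim.profiles, sim.manifest, paths["profiles"], seed=used_seed)
    aio.write_genotypes(sim.genotypes, paths["genotypes"], seed=used_seed)
    aio.write_regions(sim.regions, paths["regions"], seed=used_seed)
    with open(paths["truth_loci"], "w") as fh:
        sim.truth_loci.to_csv(fh, sep="\t", index=False)
    with open(paths["truth_samples"], "w") as fh:
        sim.truth_samples.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    write_sim_config(config, paths["config"])
    return paths
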