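"""Synthetic two-population mixed-stock genotype generator.

Emulates the sampling design the analysis pipeline assumes: two diverged
source populations ("west" and "east"), reference sampling units drawn from
each, a mechanically mixed unit containing individuals of both origins,
optional F1 hybrids, missing genotypes, monomorphic and sex-linked loci, and
inversion-linked locus blocks driven by a latent diploid inversion genotype.
Per-locus population frequencies come either from an explicit table or from
the Balding-Nichols model (Beta-distributed around an ancestral frequency
with divergence parameter F).

All randomness flows from a single seed through ``numpy.random.SeedSequence``
stream-splitting, so a config reproduces its dataset bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, LocusInfo, PanelClass, make_locus_id

WEST, EAST = "west", "east"


@dataclass
class InversionBlock:
    """A block of physically linked loci riding one chromosomal inversion.

    ``collinear_freq`` gives the frequency of the collinear (non-inverted)
    arrangement in each source population; within-block loci report the
    latent inversion genotype with probability ``concordance`` per allele.
    """

    linkage_group: int
    start_bp: int
    end_bp: int
    n_loci: int = 2
    collinear_freq_west: float = 0.8
    collinear_freq_east: float = 0.3
    concordance: float = 1.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic mixed-stock dataset.

    Defaults mirror the study design the pipeline targets: strongly
    diagnostic loci (allele-frequency difference 0.8: p_west = 0.9 vs
    p_east = 0.1), moderately diverged candidate loci drawn from the
    Balding-Nichols model, a mixed unit containing ``mixing_proportion``
    western individuals, and a low no-call rate typical of a well-behaved
    genotyping chip.
    """

    seed: int = 0
    n_diagnostic: int = 20
    n_candidate: int = 0
    n_monomorphic: int = 0
    n_sex: int = 0
    #: explicit (p_west, p_east) for diagnostic loci
    diagnostic_freqs: tuple[float, float] = (0.9, 0.1)
    #: Balding-Nichols divergence for candidate loci
    candidate_F: float = 0.25
    #: ancestral-frequency range for Balding-Nichols draws
    ancestral_range: tuple[float, float] = (0.1, 0.9)
    #: sampling unit -> (n individuals, fraction of western origin)
    units: dict = field(default_factory=lambda: {
        "REF_W": (50, 1.0), "REF_E": (50, 0.0), "MIX": (100, 0.4)})
    hybrid_fraction: float = 0.0
    missing_rate: float = 0.0
    inversion_blocks: list = field(default_factory=list)

    def __post_init__(self):
        for name, value in (("hybrid_fraction", self.hybrid_fraction),
                            ("missing_rate", self.missing_rate)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for unit, (n, frac) in self.units.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"unit {unit}: western fraction must be in [0, 1]")
        if isinstance(self.inversion_blocks, list):
            self.inversion_blocks = [
                b if isinstance(b, InversionBlock) else InversionBlock(**b)
                for b in self.inversion_blocks]

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["units"] = {k: list(v) for k, v in self.units.items()}
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            d = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        d["units"] = {k: tuple(v) for k, v in d["units"].items()}
        d["diagnostic_freqs"] = tuple(d["diagnostic_freqs"])
        d["ancestral_range"] = tuple(d["ancestral_range"])
        return cls(**d)


def balding_nichols(p_ancestral, F: float, n_pops: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw per-population allele frequencies from the Balding-Nichols model:
    ``p_pop ~ Beta(p*(1-F)/F, (1-p)*(1-F)/F)`` independently per population.

    At F -> 0 the draw collapses onto the ancestral frequency.
    """
    p = np.atleast_1d(np.asarray(p_ancestral, dtype=float))
    if not 0.0 < F < 1.0:
        if F == 0.0:
            return np.tile(p, (n_pops, 1))
        raise ValueError("F must be in [0, 1)")
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale, size=(n_pops, p.size))


def draw_population_frequencies(config: SimulationConfig,
                                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-locus (p_west, p_east) table plus the LocusInfo for every locus.

    Diagnostic loci take the configured explicit frequency pair; candidate
    loci are Balding-Nichols draws at ``candidate_F``; monomorphic loci are
    fixed in both populations; sex loci get an arbitrary polymorphic
    frequency (they are QC targets, not signal); inversion-block loci are
    handled separately in :func:`sample_individuals` through the latent
    inversion genotype but are listed here with their collinear frequencies.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    rows = []
    pos_counter = {}

    def next_pos(lg, spacing=2_000_000):
        pos_counter[lg] = pos_counter.get(lg, 0) + spacing
        return pos_counter[lg]

    lo, hi = config.ancestral_range
    for i in range(config.n_diagnostic):
        lg = (i % 20) + 1
        rows.append({"locus_id": make_locus_id(lg, next_pos(lg), PanelClass.DIAGNOSTIC),
                     "panel_class": PanelClass.DIAGNOSTIC.value,
                     "p_west": config.diagnostic_freqs[0],
                     "p_east": config.diagnostic_freqs[1]})
    if config.n_candidate:
        anc = rng.uniform(lo, hi, size=config.n_candidate)
        pw, pe = balding_nichols(anc, config.candidate_F, 2, rng)
        for i in range(config.n_candidate):
            lg = (i % 20) + 1
            rows.append({"locus_id": make_locus_id(lg, next_pos(lg), PanelClass.CANDIDATE),
                         "panel_class": PanelClass.CANDIDATE.value,
                         "p_west": pw[i], "p_east": pe[i]})
    for i in range(config.n_monomorphic):
        lg = (i % 20) + 1
        fixed = float(rng.integers(0, 2))
        rows.append({"locus_id": make_locus_id(lg, next_pos(lg), PanelClass.CANDIDATE),
                     "panel_class": PanelClass.CANDIDATE.value,
                     "p_west": fixed, "p_east": fixed})
    for i in range(config.n_sex):
        lg = 23
        rows.append({"locus_id": make_locus_id(lg, next_pos(lg), PanelClass.SEX),
                     "panel_class": PanelClass.SEX.value,
                     "p_west": 0.5, "p_east": 0.5})
    for blk in config.inversion_blocks:
        step = max(1, (blk.end_bp - blk.start_bp) // (blk.n_loci + 1))
        for i in range(blk.n_loci):
            pos = blk.start_bp + (i + 1) * step
            tag = f"I{blk.linkage_group:02d}"
            lid = f"LG{blk.linkage_group:02d}_{pos:08d}_{tag}" + ("b" if i % 2 else "")
            rows.append({"locus_id": lid, "panel_class": PanelClass.INVERSION.value,
                         "p_west": 1.0 - blk.collinear_freq_west,
                         "p_east": 1.0 - blk.collinear_freq_east})
    return pd.DataFrame(rows)


def _locus_info_from_freq_row(row) -> LocusInfo:
    overrides = {}
    if row["panel_class"] == PanelClass.INVERSION.value:
        overrides["collinear_allele"] = "ref"
    return LocusInfo.from_locus_id(row["locus_id"], **overrides)


def sample_individuals(freqs: pd.DataFrame, config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw genotypes for every sampling unit from the per-population
    frequency table.

    Pure individuals: calls ~ Binomial(2, p_origin) per locus. Individuals in
    a mixed unit are mechanically mixed: origin ~ Bernoulli(western fraction)
    and then pure sampling.  F1 hybrids draw one allele from each population.
    Inversion-block loci are derived from a latent diploid inversion genotype
    (alt = inverted arrangement) with per-allele concordance; missingness is
    MCAR at ``missing_rate``.  True origin is recorded in the metadata.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    loci = [_locus_info_from_freq_row(r) for _, r in freqs.iterrows()]
    p = freqs[["p_west", "p_east"]].to_numpy()  # (L, 2): column 0 west, 1 east
    inv_tags = freqs["panel_class"].to_numpy() == PanelClass.INVERSION.value
    block_of = {}
    for bi, blk in enumerate(config.inversion_blocks):
        for j, loc in enumerate(loci):
            if (inv_tags[j] and loc.linkage_group == blk.linkage_group
                    and blk.start_bp <= loc.position_bp <= blk.end_bp):
                block_of[j] = bi

    individuals, meta_rows, call_rows = [], [], []
    counter = 0
    for unit, (n, west_frac) in config.units.items():
        origins = np.where(rng.random(n) < west_frac, 0, 1)  # 0=west, 1=east
        hybrids = rng.random(n) < config.hybrid_fraction
        for i in range(n):
            counter += 1
            ind = f"{unit}_{counter:04d}"
            if hybrids[i]:
                a_w = rng.random(len(loci)) < p[:, 0]
                a_e = rng.random(len(loci)) < p[:, 1]
                calls = (a_w.astype(np.int8) + a_e.astype(np.int8))
                origin = "F1"
            else:
                po = p[:, origins[i]]
                calls = rng.binomial(2, po).astype(np.int8)
                origin = WEST if origins[i] == 0 else EAST
            # overwrite inversion-block loci from one latent inversion genotype
            for bi, blk in enumerate(config.inversion_blocks):
                members = [j for j, b in block_of.items() if b == bi]
                if not members:
                    continue
                if origin == "F1":
                    p_inv_w = 1.0 - blk.collinear_freq_west
                    p_inv_e = 1.0 - blk.collinear_freq_east
                    latent = int(rng.random() < p_inv_w) + int(rng.random() < p_inv_e)
                else:
                    p_inv = (1.0 - blk.collinear_freq_west if origin == WEST
                             else 1.0 - blk.collinear_freq_east)
                    latent = int(rng.binomial(2, p_inv))
                for j in members:
                    if blk.concordance >= 1.0:
                        calls[j] = latent
                    else:
                        # each allele copy reports the latent state with prob
                        # `concordance`, otherwise an independent draw
                        copies = ([1] * latent + [0] * (2 - latent))
                        reported = [
                            c if rng.random() < blk.concordance
                            else int(rng.random() < 0.5)
                            for c in copies]
                        calls[j] = int(sum(reported))
            if config.missing_rate > 0:
                calls = np.where(rng.random(len(loci)) < config.missing_rate,
                                 MISSING, calls).astype(np.int8)
            individuals.append(ind)
            call_rows.append(calls)
            meta_rows.append({"sampling_unit": unit, "true_origin": origin})
    meta = pd.DataFrame(meta_rows, index=pd.Index(individuals, name="individual"))
    return GenotypeMatrix(individuals, loci, np.stack(call_rows), meta)


def simulate(config: SimulationConfig) -> GenotypeMatrix:
    """Generate a complete dataset from a config (frequencies then genotypes),
    with deterministic stream-splitting from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    freq_rng, geno_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    freqs = draw_population_frequencies(config, freq_rng)
    return sample_individuals(freqs, config, geno_rng)


# ---------------------------------------------------------------------------
# Study-shaped fixture
# ---------------------------------------------------------------------------

#: sampling-unit sizes of the genotyped survey the pipeline emulates: six
#: units (two reference units, a mixed unit split by year, two flanking
#: units), 603 individuals in total
STUDY_UNIT_SIZES = {
    "SD22": 67, "SD23": 59, "SD24_2015": 180, "SD24_2016": 205,
    "SD25": 62, "SD26": 30,
}


def study_shaped_fixture(seed: int, mixing_proportion: float = 0.4,
                         missing_rate: float = 0.0,
                         hybrid_fraction: float = 0.0) -> GenotypeMatrix:
    """A dataset shaped like the genotyped Baltic survey: 603 individuals in
    six sampling units, a 38-locus surviving panel (20 diagnostic + 11
    candidate + 7 inversion loci in three blocks on linkage groups 2, 7 and
    12), western references in SD22/SD23, eastern in SD25/SD26, and a mixed
    Arkona-like unit (SD24, two year strata) at ``mixing_proportion``
    western origin.
    """
    units = {
        "SD22": (STUDY_UNIT_SIZES["SD22"], 1.0),
        "SD23": (STUDY_UNIT_SIZES["SD23"], 1.0),
        "SD24_2015": (STUDY_UNIT_SIZES["SD24_2015"], mixing_proportion),
        "SD24_2016": (STUDY_UNIT_SIZES["SD24_2016"], mixing_proportion),
        "SD25": (STUDY_UNIT_SIZES["SD25"], 0.0),
        "SD26": (STUDY_UNIT_SIZES["SD26"], 0.0),
    }
    blocks = [
        InversionBlock(2, 18_000_000, 21_000_000, n_loci=2,
                       collinear_freq_west=0.9, collinear_freq_east=0.2),
        InversionBlock(7, 14_000_000, 21_000_000, n_loci=3,
                       collinear_freq_west=0.8, collinear_freq_east=0.35),
        InversionBlock(12, 11_000_000, 13_000_000, n_loci=2,
                       collinear_freq_west=0.75, collinear_freq_east=0.45),
    ]
    config = SimulationConfig(
        seed=seed, n_diagnostic=20, n_candidate=11,
        diagnostic_freqs=(0.9, 0.1), candidate_F=0.25,
        units=units, missing_rate=missing_rate,
        hybrid_fraction=hybrid_fraction, inversion_blocks=blocks)
    g = simulate(config)
    year = g.metadata["sampling_unit"].map(
        lambda u: 2015 if u.endswith("2015") else 2016)
    g.metadata["year"] = year
    g.metadata["sampling_unit"] = g.metadata["sampling_unit"].str.replace(
        r"_(2015|2016)$", "", regex=True)
    g.metadata["unit_year"] = [
        f"{u} ({y})" if u == "SD24" else u
        for u, y in zip(g.metadata["sampling_unit"], g.metadata["year"])]
    return g
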