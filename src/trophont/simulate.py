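"""Seeded synthetic lake communities with known ground truth.

The generator emulates a nine-lake subarctic study system with three
community configurations — trout-only, trout + charr ("two_species"), and
trout + charr + stickleback ("three_species") — so that every downstream
stage (diet matrix, mixing model, onset and trend models, pipeline
reports) can be tested by parameter recovery:

* fork lengths: truncated lognormal (right-skewed field size structure,
  truncation standing in for gillnet selectivity);
* piscivory: per-fish Bernoulli with logit-linear probability in length
  (slope 0 disables piscivory entirely, as in trout-only systems);
* stomachs: Dirichlet prey proportions scaled to a fullness-points total,
  with a fish-prey share (Beta-distributed) present iff the piscivory
  indicator fired; a configurable fraction of stomachs is empty;
* isotopes: each fish is assigned a true trophic position (linear in
  length) and littoral reliance (Beta), its d13C/d15N generated by
  inverting the two-source mixing model against the lake's *realized*
  baseline means, then perturbed with Gaussian noise. Using realized
  (sample-mean) end-members makes zero-noise recovery exact by
  construction, which is what makes the generator a usable oracle;
* catches: Poisson counts per habitat from per-species expected CPUE.

Per-lake seeds derive from the master seed by NumPy's SeedSequence
spawning in fixed lake order, so a multi-lake study is reproducible
piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from . import isotope as iso
from .diet import PreyCategoryMap, Stomach
from .exceptions import ValidationError

__all__ = [
    "CommunityScenario",
    "LakeDataset",
    "default_prey_map",
    "default_scenarios",
    "simulate_community",
    "simulate_study",
    "write_dataset",
    "write_study",
    "read_study",
]

FISH_CATEGORY = "fish_prey"

TABLE_FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class CommunityScenario:
    """Generating parameters of one fish-community configuration."""

    name: str
    species_present: tuple[str, ...]
    n_trout: int
    length_median_mm: float
    length_sigma: float
    length_bounds_mm: tuple[float, float]
    piscivory_beta0: float
    piscivory_beta1: float  # logit slope per mm; 0 disables piscivory
    diet_concentration: dict[str, float]  # non-fish Dirichlet concentrations
    fish_share_beta: tuple[float, float] = (4.0, 2.0)
    tp_link: tuple[float, float] = (2.0, 0.002)  # TP = a + b * length
    alpha_beta: tuple[float, float] = (4.0, 2.0)  # littoral reliance dist
    isotope_noise_sd: tuple[float, float] = (0.3, 0.2)  # d13C, d15N permil
    baseline_truth: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"littoral": (-20.0, 3.0), "pelagic": (-30.0, 4.0)}
    )
    baseline_n: int = 8
    baseline_scatter_sd: float = 0.5
    cpue_truth: dict[tuple[str, str], float] = field(default_factory=dict)
    empty_stomach_prob: float = 0.1
    net_area_m2: float = 270.0
    nights: int = 2

    def __post_init__(self):
        lo, hi = self.length_bounds_mm
        if not (0 < lo < hi):
            raise ValidationError("length_bounds_mm must be positive and ordered")
        if self.n_trout < 1:
            raise ValidationError("n_trout must be >= 1")
        if self.piscivory_beta1 < 0:
            raise ValidationError("piscivory_beta1 must be >= 0")
        if not self.diet_concentration:
            raise ValidationError("diet_concentration must not be empty")
        if any(c <= 0 for c in self.diet_concentration.values()):
            raise ValidationError("diet concentrations must be strictly positive")
        if FISH_CATEGORY in self.diet_concentration:
            raise ValidationError(
                f"{FISH_CATEGORY!r} is driven by the piscivory indicator, not "
                "a Dirichlet concentration"
            )
        if not 0.0 <= self.empty_stomach_prob < 1.0:
            raise ValidationError("empty_stomach_prob must be in [0, 1)")
        if any(sd < 0 for sd in self.isotope_noise_sd):
            raise ValidationError("isotope_noise_sd must be non-negative")
        if self.name == "trout_only" and self.piscivory_beta1 != 0:
            raise ValidationError(
                "trout_only scenarios must have piscivory disabled (beta1 = 0)"
            )

    def piscivory_probability(self, length_mm) -> np.ndarray:
        length_mm = np.asarray(length_mm, dtype=float)
        if self.piscivory_beta1 == 0:
            return np.zeros_like(length_mm)
        return expit(self.piscivory_beta0 + self.piscivory_beta1 * length_mm)


@dataclass
class LakeDataset:
    """One simulated lake: the four field tables plus the truth table."""

    lake_id: str
    scenario: CommunityScenario
    fish: pd.DataFrame
    stomachs: pd.DataFrame
    baselines: pd.DataFrame
    catches: pd.DataFrame
    truth: pd.DataFrame

    def stomach_objects(self) -> list[Stomach]:
        by_fish = {}
        for row in self.stomachs.itertuples(index=False):
            by_fish.setdefault(row.fish_id, {})[row.prey_category] = row.points
        out = []
        for fid in self.fish["fish_id"]:
            pts = by_fish.get(fid, {})
            out.append(Stomach(fid, min(sum(pts.values()), 100.0), pts))
        return out


def default_prey_map() -> PreyCategoryMap:
    cats = [
        "chironomidae",
        "trichoptera",
        "ephemeroptera",
        "mollusca",
        "cladocera",
        "copepoda",
        "surface_insects",
        "unidentified",
        FISH_CATEGORY,
    ]
    return PreyCategoryMap.identity(cats, fish_prey=[FISH_CATEGORY])


def default_scenarios() -> dict[str, CommunityScenario]:
    """The three study community configurations with field-realistic
    defaults (sizes and trophic links chosen to emulate subarctic trout
    populations; see the methods note)."""
    # small concentration totals (~3) give the strong between-individual
    # diet heterogeneity (mean 1 - PS_i around 0.6) typical of these
    # generalist populations
    benthic = {
        "chironomidae": 1.0,
        "trichoptera": 0.75,
        "ephemeroptera": 0.5,
        "mollusca": 0.4,
        "surface_insects": 0.4,
        "unidentified": 0.2,
    }
    mixed = dict(benthic, cladocera=0.25, copepoda=0.2)
    return {
        "trout_only": CommunityScenario(
            name="trout_only",
            species_present=("trout",),
            n_trout=90,
            length_median_mm=170.0,
            length_sigma=0.45,
            length_bounds_mm=(80.0, 380.0),
            piscivory_beta0=0.0,
            piscivory_beta1=0.0,
            diet_concentration=dict(benthic),
            tp_link=(1.85, 0.0018),
            alpha_beta=(5.0, 2.0),
            cpue_truth={("trout", "littoral"): 4.0, ("trout", "pelagic"): 1.0},
        ),
        "two_species": CommunityScenario(
            name="two_species",
            species_present=("trout", "charr"),
            n_trout=45,
            length_median_mm=230.0,
            length_sigma=0.50,
            length_bounds_mm=(90.0, 560.0),
            piscivory_beta0=-5.4,
            piscivory_beta1=0.01,
            diet_concentration=dict(mixed),
            tp_link=(2.2, 0.0015),
            cpue_truth={
                ("trout", "littoral"): 3.0,
                ("charr", "littoral"): 3.0,
                ("charr", "profundal"): 2.0,
            },
        ),
        "three_species": CommunityScenario(
            name="three_species",
            species_present=("trout", "charr", "stickleback"),
            n_trout=74,
            length_median_mm=240.0,
            length_sigma=0.55,
            length_bounds_mm=(90.0, 650.0),
            piscivory_beta0=-3.9,
            piscivory_beta1=0.01,
            diet_concentration=dict(mixed),
            tp_link=(2.1, 0.0024),
            cpue_truth={
                ("trout", "littoral"): 3.5,
                ("trout", "pelagic"): 1.0,
                ("charr", "littoral"): 2.5,
                ("charr", "pelagic"): 1.5,
                ("charr", "profundal"): 2.0,
                ("stickleback", "littoral"): 12.0,
            },
        ),
    }


def _truncated_lognormal(rng, median, sigma, bounds, size) -> np.ndarray:
    mu = np.log(median)
    a = (np.log(bounds[0]) - mu) / sigma
    b = (np.log(bounds[1]) - mu) / sigma
    z = sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)
    return np.exp(z)


def simulate_community(
    scenario: CommunityScenario, lake_id: str, seed
) -> LakeDataset:
    """Generate one lake's dataset. Identical (scenario, lake_id, seed)
    triples produce identical datasets across process invocations."""
    rng = np.random.default_rng(seed)

    # --- baselines first: fish isotopes are generated against the
    # realized sample means, so zero-noise recovery is exact
    base_rows = []
    for habitat, (c_true, n_true) in sorted(scenario.baseline_truth.items()):
        for _ in range(scenario.baseline_n):
            base_rows.append(
                {
                    "lake_id": lake_id,
                    "habitat": habitat,
                    "d13C": c_true + rng.normal(0.0, scenario.baseline_scatter_sd),
                    "d15N": n_true + rng.normal(0.0, scenario.baseline_scatter_sd),
                }
            )
    baselines = pd.DataFrame(base_rows)
    bset = iso.aggregate_baseline(baselines, lake_id)

    # --- fish
    n = scenario.n_trout
    lengths = _truncated_lognormal(
        rng, scenario.length_median_mm, scenario.length_sigma,
        scenario.length_bounds_mm, n,
    )
    p_pisc = scenario.piscivory_probability(lengths)
    indicator = rng.random(n) < p_pisc
    tp_true = scenario.tp_link[0] + scenario.tp_link[1] * lengths
    alpha_true = rng.beta(*scenario.alpha_beta, size=n)
    d13c, d15n = iso.forward_isotopes(tp_true, alpha_true, bset)
    sd_c, sd_n = scenario.isotope_noise_sd
    d13c = d13c + rng.normal(0.0, sd_c, size=n) if sd_c > 0 else d13c
    d15n = d15n + rng.normal(0.0, sd_n, size=n) if sd_n > 0 else d15n

    fish_ids = [f"{lake_id}_F{i + 1:04d}" for i in range(n)]
    fish = pd.DataFrame(
        {
            "fish_id": fish_ids,
            "lake_id": lake_id,
            "community_type": scenario.name,
            "species": "trout",
            "fork_length_mm": lengths,
            "d13C": d13c,
            "d15N": d15n,
        }
    )

    # --- stomachs
    cats = sorted(scenario.diet_concentration)
    conc = np.array([scenario.diet_concentration[c] for c in cats])
    empty = rng.random(n) < scenario.empty_stomach_prob
    st_rows = []
    for i, fid in enumerate(fish_ids):
        if empty[i]:
            continue
        props = rng.dirichlet(conc)
        fullness = rng.uniform(10.0, 100.0)
        if indicator[i]:
            share = rng.beta(*scenario.fish_share_beta)
            share = min(max(share, 0.05), 0.95)  # keep the forced share visible
            st_rows.append(
                {"fish_id": fid, "prey_category": FISH_CATEGORY,
                 "points": share * fullness}
            )
            props = props * (1.0 - share)
        else:
            props = props.copy()
        for c, pr in zip(cats, props):
            if pr > 0:
                st_rows.append(
                    {"fish_id": fid, "prey_category": c, "points": pr * fullness}
                )
    stomachs = pd.DataFrame(st_rows, columns=["fish_id", "prey_category", "points"])

    # --- catches
    catch_rows = []
    for (species, habitat), dens in sorted(scenario.cpue_truth.items()):
        if species not in scenario.species_present:
            raise ValidationError(
                f"cpue_truth names species {species!r} absent from the community"
            )
        mean = dens / 100.0 * scenario.net_area_m2 * scenario.nights
        catch_rows.append(
            {
                "lake_id": lake_id,
                "habitat": habitat,
                "species": species,
                "count": int(rng.poisson(mean)),
                "net_area_m2": scenario.net_area_m2,
                "nights": scenario.nights,
            }
        )
    catches = pd.DataFrame(
        catch_rows,
        columns=["lake_id", "habitat", "species", "count", "net_area_m2", "nights"],
    )

    truth = pd.DataFrame(
        {
            "fish_id": fish_ids,
            "true_tp": tp_true,
            "true_alpha": alpha_true,
            "true_piscivory_prob": p_pisc,
            "piscivory_indicator": indicator.astype(int),
            "empty_stomach": empty.astype(int),
        }
    )
    return LakeDataset(lake_id, scenario, fish, stomachs, baselines, catches, truth)


def lake_seeds(master_seed: int, n_lakes: int) -> list[np.random.SeedSequence]:
    """Per-lake seeds: children of SeedSequence(master_seed) in lake order."""
    return np.random.SeedSequence(master_seed).spawn(n_lakes)


def simulate_study(
    master_seed: int,
    scenarios: dict[str, CommunityScenario] | None = None,
    lakes_per_type: int = 3,
) -> dict[str, LakeDataset]:
    """Simulate the full multi-lake study (default: 3 lakes per community
    type, mirroring the nine-lake design)."""
    scenarios = scenarios if scenarios is not None else default_scenarios()
    names = [
        (f"{sc.name}_L{i + 1}", sc)
        for sc in scenarios.values()
        for i in range(lakes_per_type)
    ]
    seeds = lake_seeds(master_seed, len(names))
    return {
        lake_id: simulate_community(sc, lake_id, seed)
        for (lake_id, sc), seed in zip(names, seeds)
    }


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=TABLE_FLOAT_FORMAT, lineterminator="\n")


def write_dataset(ds: LakeDataset, directory) -> list[Path]:
    """Write one lake's five delimited-text tables; deterministic bytes."""
    if len(ds.fish) == 0:
        raise ValidationError("refusing to write a dataset with no fish")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in [
        ("fish.csv", ds.fish),
        ("stomach.csv", ds.stomachs),
        ("baselines.csv", ds.baselines),
        ("catches.csv", ds.catches),
        ("truth.csv", ds.truth),
    ]:
        path = directory / name
        _write_csv(df, path)
        written.append(path)
    return written


def write_study(study: dict[str, LakeDataset], directory) -> list[Path]:
    """Write a multi-lake study as combined tables (one file per schema)."""
    if not study:
        raise ValidationError("empty study")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, attr in [
        ("fish.csv", "fish"),
        ("stomach.csv", "stomachs"),
        ("baselines.csv", "baselines"),
        ("catches.csv", "catches"),
        ("truth.csv", "truth"),
    ]:
        df = pd.concat([getattr(ds, attr) for ds in study.values()], ignore_index=True)
        path = directory / name
        _write_csv(df, path)
        written.append(path)
    return written


def read_study(directory) -> SimpleNamespace:
    """Read combined study tables back; truth.csv is optional."""
    directory = Path(directory)
    tables = {}
    for name in ("fish", "stomach", "baselines", "catches"):
        path = directory / f"{name}.csv"
        if not path.exists():
            raise ValidationError(f"missing input table: {path}")
        tables[name] = pd.read_csv(path)
    truth_path = directory / "truth.csv"
    tables["truth"] = pd.read_csv(truth_path) if truth_path.exists() else None
    return SimpleNamespace(
        fish=tables["fish"],
        stomachs=tables["stomach"],
        baselines=tables["baselines"],
        catches=tables["catches"],
        truth=tables["truth"],
    )


def noise_free(scenario: CommunityScenario) -> CommunityScenario:
    """Copy of a scenario with isotope noise and baseline scatter disabled
    (used by exact-inversion oracles)."""
    return replace(scenario, isotope_noise_sd=(0.0, 0.0), baseline_scatter_sd=0.0)
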