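"""Synthetic record-level and municipality-level data with planted SES strata.

The real inputs of the pipeline — a live-birth registry (gestation weeks and
mother's municipality), a population estimate table, and individual/household
socioeconomic registries — are not redistributable at record level.  This
module emulates their statistical structure: municipalities are partitioned
into latent strata, each stratum carries its own categorical SES profile and
a multiplicative effect on the per-birth preterm probability, so that the
planted stratum structure is recoverable from SES features alone and is
linked to the realised preterm municipal rate (PMR).

Two generation routes exist and agree in expectation:

* :func:`generate_municipality_table` draws the aggregated municipality
  table directly (the analogue of the pipeline's A0 input), and
* :func:`generate_microdata` draws the four record-level tables (births,
  population, persons, households) that the ingest module aggregates.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StratumSpec",
    "SynthConfig",
    "Microdata",
    "benchmark_config",
    "generate_municipality_table",
    "generate_microdata",
    "write_tables",
]

#: default categorical vocabularies (feature -> category labels).  Small
#: stand-ins for the real registries' vocabularies; the one-hot expansion is
#: comparable in spirit, not in column count, to the real data.  Everything
#: is categorical (income and rooms are bracketed) so that every aggregated
#: municipality feature is a one-hot mean in [0, 1] — the commensurability
#: the downstream unscaled PCA relies on.
PERSON_VOCABULARY: dict[str, tuple[str, ...]] = {
    "race": ("white", "black", "parda", "indigenous", "asian"),
    "education": ("none", "basic", "secondary", "higher"),
    "employment": ("formal", "informal", "unemployed"),
    "income_bracket": ("low", "mid", "high"),
}
HOUSEHOLD_VOCABULARY: dict[str, tuple[str, ...]] = {
    "water_supply": ("piped", "well", "other"),
    "sewage": ("network", "septic", "open"),
    "garbage": ("collected", "burned", "dumped"),
    "lighting": ("grid", "none"),
    "rooms_band": ("1-2", "3-4", "5+"),
}


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class StratumSpec:
    """One latent stratum: its size, SES profile and PMR linkage.

    Parameters
    ----------
    stratum_id
        Integer label returned alongside the generated tables.
    n_municipalities
        Number of municipalities drawn from this stratum.
    categorical_profile
        Mapping feature name -> probability vector over that feature's
        category vocabulary.  Each vector must sum to 1.
    pmr_multiplier
        Positive factor applied to the base per-birth preterm probability
        (on the probability scale, before the logit-noise step).
    noise_sd
        Standard deviation of Gaussian noise added on the logit of the
        preterm probability, so noise can never push it outside (0, 1).
    """

    stratum_id: int
    n_municipalities: int
    categorical_profile: Mapping[str, Sequence[float]]
    pmr_multiplier: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_municipalities < 1:
            raise ValueError("n_municipalities must be >= 1")
        if not self.pmr_multiplier > 0:
            raise ValueError("pmr_multiplier must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for feat, probs in self.categorical_profile.items():
            p = np.asarray(probs, dtype=float)
            if p.ndim != 1 or p.size == 0 or (p < 0).any():
                raise ValueError(f"invalid probability vector for {feat!r}")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"probability vector for {feat!r} sums to {p.sum()}, not 1"
                )


@dataclass(frozen=True)
class SynthConfig:
    """Full configuration of a synthetic draw.

    A fixed ``seed`` makes every generated table reproducible
    byte-for-byte.  ``base_ptb_prob`` is the per-registered-birth preterm
    probability of a multiplier-1 stratum; ``birth_rate`` is the crude
    birth rate used to size the births table (births = round(population x
    birth_rate)).  The defaults (0.01 and 0.014) put the national PMR —
    preterm births over total population — near 1.4e-4, the magnitude
    observed for Brazilian municipalities (registry under-ascertainment of
    preterm status is folded into the per-birth probability).
    """

    strata: Sequence[StratumSpec]
    base_ptb_prob: float = 0.01
    birth_rate: float = 0.014
    persons_per_municipality: int = 60
    households_per_municipality: int = 20
    population_range: tuple[int, int] = (20_000, 50_000)
    female_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum is required")
        if not 0.0 < self.base_ptb_prob < 1.0:
            raise ValueError("base_ptb_prob must lie in (0, 1)")
        max_mult = max(s.pmr_multiplier for s in self.strata)
        if self.base_ptb_prob * max_mult >= 1.0:
            raise ValueError("base_ptb_prob x max pmr_multiplier must be < 1")
        if self.birth_rate < 0:
            raise ValueError("birth_rate must be >= 0")
        lo, hi = self.population_range
        if lo <= 0 or hi < lo:
            raise ValueError("population_range must be a positive interval")
        feats = {f: len(v) for f, v in self.strata[0].categorical_profile.items()}
        for s in self.strata:
            got = {f: len(v) for f, v in s.categorical_profile.items()}
            if got != feats:
                raise ValueError("all strata must share the same vocabularies")

    @property
    def n_municipalities(self) -> int:
        return sum(s.n_municipalities for s in self.strata)

    def vocabulary(self, feature: str) -> tuple[str, ...]:
        if feature in PERSON_VOCABULARY:
            return PERSON_VOCABULARY[feature]
        if feature in HOUSEHOLD_VOCABULARY:
            return HOUSEHOLD_VOCABULARY[feature]
        n = len(self.strata[0].categorical_profile[feature])
        return tuple(f"cat{i}" for i in range(n))


@dataclass
class Microdata:
    """The four record-level tables plus the latent stratum labels."""

    births: pd.DataFrame      # TSN-like: municipality_code, weeks
    population: pd.DataFrame  # TIBGE-like: municipality_code, population
    persons: pd.DataFrame     # TP-like: person-level SES records
    households: pd.DataFrame  # TF-like: household-level SES records
    labels: pd.Series         # stratum id per municipality_code


def _stratum_profile(stratum: int, feature: str, n_cats: int) -> np.ndarray:
    """Deterministic distinct profile: one dominant category per stratum."""
    dominant = (stratum + sum(feature.encode()) % n_cats) % n_cats
    p = np.full(n_cats, 0.45 / (n_cats - 1)) if n_cats > 1 else np.array([1.0])
    if n_cats > 1:
        p[dominant] = 0.55
    return p


def benchmark_config(
    n_per_stratum: int = 100,
    seed: int = 0,
    multipliers: Sequence[float] = (2.0, 1.6, 0.55, 0.35),
    noise_sd: float = 0.05,
    **overrides,
) -> SynthConfig:
    """The four-stratum recovery benchmark: two high-PMR and two low-PMR
    strata with clearly separated SES profiles.

    Profiles are deterministic (independent of ``seed``): stratum *s*
    concentrates 55% of the mass of each categorical feature on one
    stratum-specific category, the rest spread uniformly.
    """
    features = {**PERSON_VOCABULARY, **HOUSEHOLD_VOCABULARY}
    strata = []
    for s, mult in enumerate(multipliers):
        profile = {
            feat: _stratum_profile(s, feat, len(cats))
            for feat, cats in features.items()
        }
        strata.append(
            StratumSpec(
                stratum_id=s,
                n_municipalities=n_per_stratum,
                categorical_profile=profile,
                pmr_multiplier=mult,
                noise_sd=noise_sd,
            )
        )
    return SynthConfig(strata=strata, seed=seed, **overrides)


def _municipality_frame(config: SynthConfig, rng: np.random.Generator):
    """Draw per-municipality latent quantities shared by both routes."""
    rows = []
    for spec in config.strata:
        base = _logit(config.base_ptb_prob * spec.pmr_multiplier)
        for _ in range(spec.n_municipalities):
            pop = int(rng.integers(*config.population_range, endpoint=True))
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            p = float(_expit(np.array(base + noise)))
            rows.append((spec.stratum_id, pop, p))
    codes = [f"M{i:05d}" for i in range(len(rows))]
    frame = pd.DataFrame(rows, columns=["stratum", "population", "ptb_prob"])
    frame.insert(0, "municipality_code", codes)
    return frame


def _one_hot_columns(config: SynthConfig, vocab: Mapping[str, tuple[str, ...]]):
    return [(feat, cat) for feat in vocab for cat in config.vocabulary(feat)]


def generate_municipality_table(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the aggregated municipality table directly.

    Returns the table (one row per municipality: ``municipality_code``,
    ``PMR``, then SES feature means) and a Series of latent stratum labels
    indexed by municipality code.  Labels are never written into the
    feature columns.
    """
    rng = np.random.default_rng(config.seed)
    latent = _municipality_frame(config, rng)

    births = np.rint(latent["population"].to_numpy() * config.birth_rate).astype(int)
    preterm = rng.binomial(births, latent["ptb_prob"].to_numpy())
    pmr = preterm / latent["population"].to_numpy()

    data: dict[str, np.ndarray] = {"PMR": pmr}
    strat_by_id = {s.stratum_id: s for s in config.strata}
    strat_arr = latent["stratum"].to_numpy()

    for vocab, count in (
        (PERSON_VOCABULARY, config.persons_per_municipality),
        (HOUSEHOLD_VOCABULARY, config.households_per_municipality),
    ):
        for feat in vocab:
            cats = config.vocabulary(feat)
            means = np.empty((len(latent), len(cats)))
            for i, s_id in enumerate(strat_arr):
                probs = np.asarray(
                    strat_by_id[s_id].categorical_profile[feat], dtype=float
                )
                means[i] = rng.multinomial(count, probs) / count
            for j, cat in enumerate(cats):
                data[f"{feat}={cat}"] = means[:, j]

    table = pd.DataFrame(data)
    table.insert(0, "municipality_code", latent["municipality_code"])
    labels = pd.Series(
        strat_arr, index=latent["municipality_code"], name="stratum"
    )
    return table, labels


def generate_microdata(config: SynthConfig) -> Microdata:
    """Draw the four record-level tables.

    Births carry gestation weeks (term >= 37 weeks, preterm < 37, with the
    municipality's per-birth preterm probability); the population table is
    the PMR denominator; every person row references a household row of the
    same municipality; categorical values follow the stratum's profile.
    """
    rng = np.random.default_rng(config.seed)
    latent = _municipality_frame(config, rng)
    strat_by_id = {s.stratum_id: s for s in config.strata}

    birth_rows: list[tuple[str, int]] = []
    person_frames: list[pd.DataFrame] = []
    household_frames: list[pd.DataFrame] = []

    for _, row in latent.iterrows():
        code, stratum, pop, p = (
            row["municipality_code"],
            row["stratum"],
            int(row["population"]),
            row["ptb_prob"],
        )
        profile = strat_by_id[stratum].categorical_profile

        n_births = int(round(pop * config.birth_rate))
        if n_births > 0:
            is_pre = rng.random(n_births) < p
            weeks = np.where(
                is_pre,
                rng.integers(22, 37, size=n_births),
                rng.integers(37, 43, size=n_births),
            )
            birth_rows.extend((code, int(w)) for w in weeks)

        n_h = config.households_per_municipality
        hh_ids = [f"{code}H{j:03d}" for j in range(n_h)]
        hh = {"household_id": hh_ids, "municipality_code": code}
        for feat in HOUSEHOLD_VOCABULARY:
            cats = config.vocabulary(feat)
            hh[feat] = rng.choice(
                cats, size=n_h, p=np.asarray(profile[feat], dtype=float)
            )
        household_frames.append(pd.DataFrame(hh))

        n_p = config.persons_per_municipality
        pp = {
            "person_id": [f"{code}P{j:04d}" for j in range(n_p)],
            "household_id": rng.choice(hh_ids, size=n_p),
            "municipality_code": code,
            "gender": np.where(
                rng.random(n_p) < config.female_frac, "female", "male"
            ),
            "age": rng.integers(10, 61, size=n_p),
        }
        for feat in PERSON_VOCABULARY:
            cats = config.vocabulary(feat)
            pp[feat] = rng.choice(
                cats, size=n_p, p=np.asarray(profile[feat], dtype=float)
            )
        person_frames.append(pd.DataFrame(pp))

    births = pd.DataFrame(birth_rows, columns=["municipality_code", "weeks"])
    population = latent[["municipality_code", "population"]].copy()
    persons = pd.concat(person_frames, ignore_index=True)
    households = pd.concat(household_frames, ignore_index=True)
    labels = pd.Series(
        latent["stratum"].to_numpy(),
        index=latent["municipality_code"],
        name="stratum",
    )
    return Microdata(births, population, persons, households, labels)


def write_tables(outdir, micro: Microdata, config: SynthConfig) -> None:
    """Write the four tables (headered CSV) plus a YAML manifest recording
    the full configuration and seed; latent labels go to a separate file."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    micro.births.to_csv(out / "tsn.csv", index=False)
    micro.population.to_csv(out / "tibge.csv", index=False)
    micro.persons.to_csv(out / "tp.csv", index=False)
    micro.households.to_csv(out / "tf.csv", index=False)
    micro.labels.rename_axis("municipality_code").reset_index().to_csv(
        out / "true_strata.csv", index=False
    )
    manifest = {
        "seed": config.seed,
        "config": _config_dict(config),
        "tables": {
            "tsn.csv": list(micro.births.shape),
            "tibge.csv": list(micro.population.shape),
            "tp.csv": list(micro.persons.shape),
            "tf.csv": list(micro.households.shape),
        },
    }
    with open(out / "synth_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def _config_dict(config: SynthConfig) -> dict:
    d = dataclasses.asdict(config)
    for s in d["strata"]:
        s["categorical_profile"] = {
            k: [float(x) for x in v] for k, v in s["categorical_profile"].items()
        }
    d["population_range"] = list(d["population_range"])
    return d
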