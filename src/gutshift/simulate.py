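"""Synthetic paired dietary-intervention study generator.

Emulates a two-breed, two-body-condition (lean/normal vs overweight), two-diet
(high-protein/low-carbohydrate vs lower-protein/higher-carbohydrate) crossover-free
intervention: every dog contributes one baseline sample on a common Base diet and one
post-intervention sample on its randomly assigned diet.  Taxon loads are log-normal with
a per-dog random effect (inducing the paired structure), planted diet effects act as
log2 fold changes on absolute loads, loads are closed to relative abundances, and values
below a relative-abundance detection limit are recorded as zero — the same censoring
mechanism the downstream doubly-censored ratio tests are built for.

Every draw flows through one :class:`numpy.random.Generator` seeded from the config, so
a given config reproduces its dataset bit for bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StudyConfig",
    "SimulatedStudy",
    "demo_study_config",
    "simulate_study",
    "simulate_marker_genes",
    "simulate_allele_freqs",
    "maintenance_energy",
]

DIETS = ("Base", "HPLC", "LPHC")
CONDITIONS = ("LN", "OW")


@dataclass
class StudyConfig:
    """Parameters of a synthetic paired intervention study.

    Parameters
    ----------
    n_dogs:
        Number of animals; each contributes a baseline and a post sample.
    breeds:
        Breed labels cycled over the dogs.
    condition_fraction_ow:
        Fraction of dogs in the overweight/obese (OW) body-condition group.
    diets:
        Intervention diet labels assigned (balanced, randomized) at the post timepoint.
    n_taxa:
        Number of taxa (features) in the abundance table.
    detection_limit:
        Relative abundance below which an observation is recorded as exactly 0.
    effect_map:
        ``{taxon: {diet: log2 fold change}}`` planted on absolute loads post-intervention.
    ow_response_multiplier:
        Scales planted HPLC effects for OW dogs (>=1); models the stronger response of
        overweight animals to the high-protein intervention.
    dog_effect_sd:
        SD (log10 scale) of the per-dog, per-taxon random effect shared by both
        timepoints of a dog.
    noise_sd:
        SD (log10 scale) of independent per-sample noise.
    base_mean_sd:
        SD (log10 scale) of the taxon base means; controls how long-tailed the
        community is.
    seed:
        Seed for the single random generator used throughout.
    """

    n_dogs: int = 64
    breeds: Sequence[str] = ("Labrador", "Beagle")
    condition_fraction_ow: float = 0.5
    diets: Sequence[str] = ("HPLC", "LPHC")
    n_taxa: int = 60
    detection_limit: float = 2e-5
    effect_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    ow_response_multiplier: float = 1.0
    dog_effect_sd: float = 0.4
    noise_sd: float = 0.25
    base_mean_sd: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dogs < 2:
            raise ValueError("n_dogs must be >= 2")
        if not (0.0 < self.detection_limit < 1.0):
            raise ValueError("detection_limit must lie in (0, 1)")
        for taxon, per_diet in self.effect_map.items():
            for diet, lfc in per_diet.items():
                if not np.isfinite(lfc):
                    raise ValueError(f"non-finite fold change for {taxon}/{diet}")

    def taxa(self) -> list[str]:
        return [f"taxon_{i:03d}" for i in range(self.n_taxa)]

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["breeds"] = list(self.breeds)
        d["diets"] = list(self.diets)
        d["effect_map"] = {t: dict(m) for t, m in self.effect_map.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate_study`.

    ``abundance`` is taxon x sample relative abundance (columns sum to 1 before
    detection-limit zeroing); ``metadata`` is one row per sample; ``truth`` records the
    planted per-dog, per-taxon log2 effects and the generator's assignments.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.abundance.to_csv(outdir / "abundance.tsv", sep="\t")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))


def demo_study_config(seed: int = 0, n_dogs: int = 64) -> StudyConfig:
    """The package's reference intervention scenario.

    Diet effects concentrated on a handful of taxa, the high-protein intervention more
    drastic than the high-carbohydrate one (stronger and more numerous fold changes),
    and a doubled response in overweight dogs under the high-protein diet — the
    qualitative structure of the dog-diet intervention the package is built to analyse.
    """
    hplc_lfc = [2.5, -2.0, 2.0, 1.5, -1.5, 2.0, -2.5, 1.5, 2.0, -2.0]
    effect_map: dict[str, dict[str, float]] = {
        f"taxon_{i:03d}": {"HPLC": lfc} for i, lfc in enumerate(hplc_lfc)
    }
    for t in range(10, 14):
        effect_map[f"taxon_{t:03d}"] = {"LPHC": 0.8 if t % 2 else -0.8}
    return StudyConfig(
        n_dogs=n_dogs,
        n_taxa=60,
        detection_limit=2e-5,
        effect_map=effect_map,
        ow_response_multiplier=2.0,
        seed=seed,
    )


def _make_metadata(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_dogs
    dogs = [f"dog_{i:03d}" for i in range(n)]
    breeds = [config.breeds[i % len(config.breeds)] for i in range(n)]
    sexes = [("F", "M")[i % 2] for i in range(n)]
    n_ow = int(round(config.condition_fraction_ow * n))
    conditions = np.array(["OW"] * n_ow + ["LN"] * (n - n_ow))
    rng.shuffle(conditions)
    # balanced random diet assignment within condition groups (mirrors stratified
    # randomization of the study design)
    diets = np.empty(n, dtype=object)
    for cond in CONDITIONS:
        idx = np.flatnonzero(conditions == cond)
        assigned = np.array(
            [config.diets[i % len(config.diets)] for i in range(len(idx))], dtype=object
        )
        rng.shuffle(assigned)
        diets[idx] = assigned
    cohorts = np.array([1 + (i % 2) for i in range(n)])
    rng.shuffle(cohorts)

    rows = []
    for i, dog in enumerate(dogs):
        for timepoint in ("baseline", "post"):
            rows.append(
                {
                    "sample_id": f"{dog}_{timepoint}",
                    "dog_id": dog,
                    "breed": breeds[i],
                    "sex": sexes[i],
                    "condition": conditions[i],
                    "diet": "Base" if timepoint == "baseline" else diets[i],
                    "timepoint": timepoint,
                    "cohort": int(cohorts[i]),
                }
            )
    return pd.DataFrame(rows)


def simulate_study(config: StudyConfig) -> SimulatedStudy:
    """Generate a paired-design abundance table with known planted diet effects.

    Baseline log10 load of taxon *t* in dog *d* is ``mu_t + a_{d,t} + eps`` with
    ``a`` the dog random effect and ``eps`` sample noise; the post sample multiplies
    the load by ``2**effect`` where the planted effect for OW dogs on HPLC is scaled
    by ``ow_response_multiplier``.  Loads are closed per sample to relative abundances
    and entries below ``detection_limit`` are set to exactly 0.
    """
    taxa = config.taxa()
    unknown = set(config.effect_map) - set(taxa)
    if unknown:
        raise KeyError(f"effect_map references unknown taxa: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    metadata = _make_metadata(config, rng)
    dogs = metadata["dog_id"].unique()
    n_taxa = len(taxa)

    mu = rng.normal(0.0, config.base_mean_sd, size=n_taxa)  # log10 taxon base means
    dog_effect = rng.normal(0.0, config.dog_effect_sd, size=(len(dogs), n_taxa))

    dog_rows = metadata.drop_duplicates("dog_id").set_index("dog_id")
    taxon_index = {t: i for i, t in enumerate(taxa)}

    # planted per-dog, per-taxon log2 effects (the truth record)
    effects = np.zeros((len(dogs), n_taxa))
    for d_i, dog in enumerate(dogs):
        diet = metadata.loc[
            (metadata.dog_id == dog) & (metadata.timepoint == "post"), "diet"
        ].item()
        condition = dog_rows.loc[dog, "condition"]
        for taxon, per_diet in config.effect_map.items():
            lfc = per_diet.get(diet, 0.0)
            if diet == "HPLC" and condition == "OW":
                lfc *= config.ow_response_multiplier
            effects[d_i, taxon_index[taxon]] = lfc

    columns = {}
    log2_10 = np.log2(10.0)
    for d_i, dog in enumerate(dogs):
        base_log10 = mu + dog_effect[d_i]
        for timepoint in ("baseline", "post"):
            noise = rng.normal(0.0, config.noise_sd, size=n_taxa)
            log10_load = base_log10 + noise
            if timepoint == "post":
                log10_load = log10_load + effects[d_i] / log2_10
            load = 10.0 ** log10_load
            rel = load / load.sum()
            rel[rel < config.detection_limit] = 0.0
            columns[f"{dog}_{timepoint}"] = rel

    abundance = pd.DataFrame(columns, index=taxa)
    abundance = abundance[metadata["sample_id"].tolist()]
    abundance.index.name = "taxon"

    truth = {
        "effect_map": {t: dict(m) for t, m in config.effect_map.items()},
        "ow_response_multiplier": config.ow_response_multiplier,
        "detection_limit": config.detection_limit,
        "per_dog_effects": {
            dog: {
                taxa[t_i]: float(effects[d_i, t_i])
                for t_i in range(n_taxa)
                if effects[d_i, t_i] != 0.0
            }
            for d_i, dog in enumerate(dogs)
        },
        "diet_by_dog": {
            dog: metadata.loc[
                (metadata.dog_id == dog) & (metadata.timepoint == "post"), "diet"
            ].item()
            for dog in dogs
        },
        "condition_by_dog": {dog: dog_rows.loc[dog, "condition"] for dog in dogs},
        "seed": config.seed,
    }
    return SimulatedStudy(abundance=abundance, metadata=metadata, truth=truth)


def simulate_marker_genes(
    species_abundance: pd.DataFrame,
    n_families: int = 10,
    length_range: tuple[int, int] = (600, 1500),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Emit single-copy marker genes for each species in an abundance table.

    Each species contributes one gene per family; the gene's per-sample base-scaled
    count is ``species load x gene length x lognormal noise``.  Returns a marker-gene
    table (columns ``gene``, ``family``, ``length`` then one column per sample) and the
    gene -> true-species map used as ground truth by linkage-recovery tests.
    """
    if species_abundance.shape[0] == 0:
        raise ValueError("species_abundance has no species")
    if n_families < 2:
        raise ValueError("n_families must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    rows = []
    truth: dict[str, str] = {}
    for species in species_abundance.index:
        load = species_abundance.loc[species].to_numpy(dtype=float)
        for fam in range(n_families):
            gene = f"{species}.MG{fam:02d}"
            length = int(rng.integers(lo, hi + 1))
            noise = np.exp(rng.normal(0.0, noise_sd, size=load.shape)) if noise_sd > 0 else 1.0
            counts = load * length * noise
            rows.append([gene, f"COG{fam:04d}", length, *counts])
            truth[gene] = str(species)
    table = pd.DataFrame(
        rows, columns=["gene", "family", "length", *species_abundance.columns]
    ).set_index("gene")
    return table, truth


def simulate_allele_freqs(
    n_group_a: int,
    n_group_b: int,
    n_positions: int,
    within_sd: float = 0.05,
    between_shift: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two host groups of SNP allele-frequency profiles with a controllable mean shift.

    Group A samples scatter around a random base frequency profile; group B around the
    base shifted by ``between_shift`` at every position (clipped into [0, 1] with a
    warning if the shift pushes means outside the unit interval).  Returns a
    position x sample frequency matrix and a sample -> group label Series.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.1, 0.9, size=n_positions)
    shifted = base + between_shift
    if ((shifted < 0) | (shifted > 1)).any():
        warnings.warn("between_shift pushes group means outside [0, 1]; clipping")
        shifted = np.clip(shifted, 0.0, 1.0)

    cols = {}
    labels = {}
    for i in range(n_group_a):
        f = base + rng.normal(0.0, within_sd, size=n_positions) if within_sd > 0 else base
        cols[f"A_{i:02d}"] = np.clip(f, 0.0, 1.0)
        labels[f"A_{i:02d}"] = "A"
    for i in range(n_group_b):
        f = (
            shifted + rng.normal(0.0, within_sd, size=n_positions)
            if within_sd > 0
            else shifted.copy()
        )
        cols[f"B_{i:02d}"] = np.clip(f, 0.0, 1.0)
        labels[f"B_{i:02d}"] = "B"
    freqs = pd.DataFrame(cols, index=[f"pos_{i:05d}" for i in range(n_positions)])
    return freqs, pd.Series(labels, name="host")


def maintenance_energy(body_weight_kg: float, exponent: float = 0.75) -> float:
    """Daily maintenance energy requirement, kcal: ``139 * BW**exponent``.

    The 0.75 default is the conventional allometric metabolic-scaling exponent.
    """
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    return 139.0 * body_weight_kg**exponent
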