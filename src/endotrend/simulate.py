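"""Synthetic museum-record generator with known ground truth.

Emulates the statistical structure the analysis assumes: a set of bird
and mammal species, each aquatic or terrestrial, with a cloud of dated,
geo-referenced, sexed body-mass records; a habitat-dependent (and
optionally period-dependent) linear year effect on standardized mass;
absolute-latitude and sex effects; a phylogenetically correlated species
random intercept drawn from N(0, sigma_a^2 A); and Gaussian residual
noise. Standardized values are mapped to grams through a per-species mean
mass and coefficient of variation, so the full pipeline (filters, trend
fits, mixed models) runs on realistic-looking tables.

The default configuration mirrors the shape of the real study: 44
species in class-habitat cells of 10 aquatic birds, 17 terrestrial birds,
4 aquatic mammals and 13 terrestrial mammals; collection years within
1915-2013; aquatic mass gently increasing (+0.003 sd/yr) and terrestrial
mass flat before 1950 and declining (-0.006 sd/yr) after.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .pglmm import phylo_covariance
from .records import RecordTable, SpeciesMeta
from .trees import parse_newick

DEFAULT_CELLS = {("bird", "aquatic"): 10, ("bird", "terrestrial"): 17,
                 ("mammal", "aquatic"): 4, ("mammal", "terrestrial"): 13}


@dataclass
class SimConfig:
    """Generator settings; every field is realized into the ground truth.

    Trends are in standardized-mass units per year; a scalar means one
    slope for the whole span, a ``(pre, post)`` pair switches slope at
    ``period_boundary`` (the trend term is a hinge, continuous at the
    boundary).
    """

    n_species: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    n_records_range: tuple = (150, 600)
    first_year_range: tuple = (1915, 1960)
    last_year: int = 2013
    period_boundary: int = 1950
    trend_aquatic: float | tuple = 0.003
    trend_terrestrial: float | tuple = (0.0, -0.006)
    beta_abs_latitude: float = 0.011
    beta_sex_male: float = 0.046
    sigma_a2: float = 0.2
    sigma_e2: float = 1.0
    mean_mass_range: tuple = (5.0, 5e5)   # grams, log-uniform
    mass_cv: float = 0.1
    lat_range: tuple = (30.0, 70.0)
    lon_range: tuple = (-130.0, -95.0)
    sampling_mode: str = "uniform"        # or "era_biased"
    scaling: str = "unit_diagonal"
    seed: int = 0

    def __post_init__(self):
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variances must be nonnegative")
        if self.sampling_mode not in ("uniform", "era_biased"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")

    @property
    def total_species(self) -> int:
        return sum(self.n_species.values())


@dataclass
class GroundTruth:
    """Everything that was drawn: parameters plus realized latent values."""

    config: dict
    species: dict          # species_id -> {class, habitat, mean_mass, ...}
    species_effects: dict  # species_id -> latent intercept (sd units)

    def to_json(self, path) -> None:
        cfg = dict(self.config)
        cfg["n_species"] = {"|".join(k): v
                            for k, v in cfg["n_species"].items()}
        Path(path).write_text(json.dumps(
            {"config": cfg, "species": self.species,
             "species_effects": self.species_effects},
            indent=2, default=str))


def simulate_tree(n_tips: int, seed: int = 0, labels=None) -> dendropy.Tree:
    """Random bifurcating topology with all branch lengths 1.

    Built by repeated random joins; the same seed reproduces the same
    Newick string exactly.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("labels must match n_tips")
    items = [f"{lb}:1" for lb in labels]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = f"({items[i]},{items[j]}):1"
        items = [it for k, it in enumerate(items) if k not in (i, j)]
        items.append(merged)
    newick = items[0].rsplit(":", 1)[0] + ";"
    return parse_newick(newick)


def _trend_term(years: np.ndarray, trend, boundary: int) -> np.ndarray:
    """Hinge trend centered at the boundary year."""
    t = years.astype(float) - boundary
    if np.isscalar(trend):
        return trend * t
    pre, post = trend
    return np.where(t <= 0, pre * t, post * t)


def simulate_records(config: SimConfig, tree: dendropy.Tree | None = None
                     ) -> tuple[RecordTable, dict, GroundTruth]:
    """Draw a record table, species metadata and ground truth.

    Returns ``(records, meta, truth)`` where ``meta`` maps species_id to
    :class:`~endotrend.records.SpeciesMeta`. If no tree is given, one is
    simulated (same seed family as the records).
    """
    rng = np.random.default_rng(config.seed)
    m = config.total_species
    labels = [f"sp{i + 1:02d}" for i in range(m)]
    if tree is None:
        tree = simulate_tree(m, seed=config.seed + 1, labels=labels)
    cov = phylo_covariance(tree, scaling=config.scaling, species_order=labels)

    # phylogenetically correlated species intercepts
    if config.sigma_a2 > 0:
        L = np.linalg.cholesky(cov.matrix + 1e-10 * np.eye(m))
        u = np.sqrt(config.sigma_a2) * (L @ rng.standard_normal(m))
    else:
        u = np.zeros(m)

    cells = [cell for cell, k in config.n_species.items() for _ in range(k)]
    log_lo, log_hi = np.log(config.mean_mass_range)
    mean_mass = np.exp(rng.uniform(log_lo, log_hi, size=m))

    frames, species_info, meta = [], {}, {}
    for i, (sp, (cls, hab)) in enumerate(zip(labels, cells)):
        n = int(rng.integers(config.n_records_range[0],
                             config.n_records_range[1] + 1))
        first = int(rng.integers(config.first_year_range[0],
                                 config.first_year_range[1] + 1))
        span = np.arange(first, config.last_year + 1)
        if config.sampling_mode == "era_biased":
            w = np.linspace(1.0, 3.0, len(span))
            years = rng.choice(span, size=n, p=w / w.sum())
        else:
            years = rng.choice(span, size=n)
        lat = rng.uniform(*config.lat_range, size=n)
        lon = rng.uniform(*config.lon_range, size=n)
        male = rng.integers(0, 2, size=n)
        trend = (config.trend_aquatic if hab == "aquatic"
                 else config.trend_terrestrial)
        z = (_trend_term(years, trend, config.period_boundary)
             + config.beta_abs_latitude * np.abs(lat)
             + config.beta_sex_male * male
             + u[i]
             + np.sqrt(config.sigma_e2) * rng.standard_normal(n))
        mass = mean_mass[i] * (1.0 + config.mass_cv * z)
        frames.append(pd.DataFrame({
            "species_id": sp, "mass": mass, "year": years.astype(int),
            "latitude": lat, "longitude": lon,
            "sex": np.where(male == 1, "male", "female")}))
        species_info[sp] = {"taxo_class": cls, "habitat": hab,
                            "mean_mass": float(mean_mass[i]),
                            "n_records": n, "first_year": first,
                            "last_year": config.last_year,
                            "trend": trend}
        meta[sp] = SpeciesMeta(species_id=sp, taxo_class=cls, habitat=hab,
                               n_records=n, first_year=int(years.min()),
                               last_year=int(years.max()))

    records = RecordTable(pd.concat(frames, ignore_index=True),
                          source="synthetic")
    records.log("simulate", n_records=len(records), seed=config.seed)
    truth = GroundTruth(config=asdict(config), species=species_info,
                        species_effects={sp: float(u[i])
                                         for i, sp in enumerate(labels)})
    return records, meta, truth


def write_dataset(outdir, records: RecordTable, meta: dict,
                  tree: dendropy.Tree, truth: GroundTruth) -> None:
    """Write records CSV, metadata CSV, Newick tree and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records.to_csv(outdir / "records.csv")
    pd.DataFrame([
        {"species_id": s, "class": m.taxo_class, "habitat": m.habitat}
        for s, m in meta.items()
    ]).to_csv(outdir / "species_meta.csv", index=False)
    tree.write(path=str(outdir / "tree.nwk"), schema="newick",
               suppress_rooting=True)
    truth.to_json(outdir / "ground_truth.json")
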