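"""Synthetic multi-generation tuber microbiome datasets with known truth.

The generator emulates the processed-data structure of a three-generation
seed-potato trial: seed tubers (no field), daughter tubers grown at a
single field, and granddaughter tubers grown at two fields, each sampled
in flesh and peel compartments (plus tare soil at the granddaughter
stage), for two cultivars with ~10 replicate tubers per design cell.

Community structure:

* each cultivar's seed tubers carry a compartment-specific founder pool
  whose taxa have baseline log10 relative abundances drawn from a normal
  distribution;
* each founder taxon is independently retained into the next generation's
  same compartment with a per-compartment retention probability, chained
  across the two transitions (the vertical core);
* every later (generation, compartment, field) cell additionally receives
  a pool of newly acquired horizontal taxa, larger in peel than flesh and
  growing across generations; the tare-soil pool shares a configurable
  fraction of taxa with the same field's granddaughter peel pool;
* retained non-null taxa get a per-(taxon, generation) abundance offset
  with variance ``vg`` shared by all samples of that generation, plus a
  per-sample residual with variance ``ve`` — so the one-way
  random-effects model used for heritability is exactly the generating
  model, with true H2 = vg / (vg + ve) (0 for the null fraction);
* per-sample relative abundances are renormalized and converted to reads
  by a lognormal library size and gamma-Poisson (negative binomial)
  count sampling;
* with the detection guarantee on (default), every taxon marked present
  in a cell receives at least one read in each of that cell's samples,
  so presence/absence classification can be checked against the truth
  ledger without stochastic detection noise.

Every draw flows from a single :class:`numpy.random.Generator` seeded by
``rng_seed``; identical configurations give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    GENERATIONS,
    NO_FIELD,
    CountTable,
    Dataset,
    SampleMetadata,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_dataset",
    "truth_report",
    "simulate_retention_trials",
    "simulate_abundance_matrix",
]


def _default_horizontal_pools(
    generations: Sequence[str], fields: Sequence[str]
) -> dict[tuple[str, str, str], int]:
    """Default horizontal pool sizes per (generation, compartment, field).

    Daughter tubers grow at the first field only; granddaughters at both.
    Pools increase across generations and are larger in peel than flesh,
    with a large field-specific tare-soil pool at the granddaughter stage.
    """
    pools: dict[tuple[str, str, str], int] = {}
    if len(generations) > 1:
        pools[(generations[1], "flesh", fields[0])] = 250
        pools[(generations[1], "peel", fields[0])] = 500
    for g in generations[2:]:
        for f in fields:
            pools[(g, "flesh", f)] = 400
            pools[(g, "peel", f)] = 1200
            pools[(g, "tare_soil", f)] = 1500
    return pools


@dataclass
class SimulationConfig:
    """Study-design and distributional parameters of the generator.

    Defaults mirror the emulated trial: 10 replicate tubers per cell,
    two cultivars, two fields, founder richness of a few hundred taxa
    per cultivar, modest per-transition retention (higher in flesh than
    peel), and horizontally acquired pools that grow across generations
    and dominate in peel.
    """

    seed_richness_flesh: int = 120
    seed_richness_peel: int = 200
    #: per-transition probability that a founder taxon is retained into
    #: the next generation's same compartment
    retention_prob: dict[str, float] = dc_field(
        default_factory=lambda: {"flesh": 0.20, "peel": 0.15}
    )
    #: newly acquired taxa per (generation, compartment, field) cell
    horizontal_pool_size: Optional[dict[tuple[str, str, str], int]] = None
    n_replicates: int = 10
    generations: tuple[str, ...] = GENERATIONS
    cultivars: tuple[str, ...] = ("Nadine", "Royal_Blue")
    fields: tuple[str, ...] = ("Brunswick", "Murdoch")
    #: fraction of each field's granddaughter peel pool also present in
    #: that field's tare soil
    tare_soil_peel_overlap: float = 0.4
    #: between-generation and residual variance of log10 abundance for
    #: retained (vertical-core) taxa
    vg: float = 0.4
    ve: float = 0.4
    #: fraction of the vertical core simulated with VG = 0
    null_fraction: float = 0.35
    #: baseline log10 relative abundance ~ Normal(baseline_mean, baseline_sd)
    baseline_mean: float = -3.0
    baseline_sd: float = 1.0
    library_size_mean: float = 30000.0
    #: sigma of the lognormal library-size distribution
    library_size_shape: float = 0.3
    #: gamma-Poisson overdispersion: Var = mu + dispersion * mu^2
    dispersion: float = 0.1
    detection_guarantee: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.horizontal_pool_size is None:
            self.horizontal_pool_size = _default_horizontal_pools(
                self.generations, self.fields
            )
        for c, p in self.retention_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"retention_prob[{c!r}] = {p} outside [0, 1]")
        if not 0.0 <= self.tare_soil_peel_overlap <= 1.0:
            raise ValueError("tare_soil_peel_overlap must be in [0, 1]")
        if not 0.0 <= self.null_fraction <= 1.0:
            raise ValueError("null_fraction must be in [0, 1]")
        if self.vg < 0 or self.ve < 0:
            raise ValueError("vg and ve must be nonnegative")
        if self.null_fraction < 1.0 and self.vg + self.ve == 0:
            raise ValueError("vg + ve must be positive for non-null taxa")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        if self.seed_richness_flesh < 1 or self.seed_richness_peel < 1:
            raise ValueError("seed richness must be positive")
        if len(self.generations) < 1 or len(self.cultivars) < 1:
            raise ValueError("need at least one generation and one cultivar")
        if self.library_size_mean <= 0 or self.library_size_shape <= 0:
            raise ValueError("library size parameters must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class SimulationTruth:
    """Ground-truth ledger of a simulated dataset.

    ``taxa`` has one row per simulated taxon: its cultivar, compartment
    of origin, origin label (``vertical_core`` or ``horizontal``), origin
    generation and field, true H2 (NaN for horizontal taxa), and the
    semicolon-joined ``generation:compartment:field`` cells where it is
    present.  ``retention_prob`` repeats the generating per-compartment
    retention probabilities.
    """

    taxa: pd.DataFrame
    retention_prob: dict[str, float]

    def presence_cells(self, taxon_id: str) -> set[tuple[str, str, str]]:
        row = self.taxa.loc[self.taxa["taxon_id"] == taxon_id].iloc[0]
        return _parse_cells(row["retained_in"])

    def vertical_taxa(self, cultivar: str, compartment: str) -> set[str]:
        t = self.taxa
        sel = (
            (t["origin"] == "vertical_core")
            & (t["cultivar"] == cultivar)
            & (t["compartment"] == compartment)
        )
        return set(t.loc[sel, "taxon_id"])


def _parse_cells(s: str) -> set[tuple[str, str, str]]:
    if not s:
        return set()
    return {tuple(cell.split(":")) for cell in s.split(";")}  # type: ignore[return-value]


def _format_cells(cells: Sequence[tuple[str, str, str]]) -> str:
    return ";".join(":".join(c) for c in sorted(cells))


@dataclass
class _Taxon:
    taxon_id: str
    cultivar: str
    compartment: str
    origin: str
    origin_generation: str
    origin_field: str
    true_h2: float
    baseline: float
    gen_offsets: dict[str, float]
    cells: list[tuple[str, str, str]]


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, SimulationTruth]:
    """Generate a dataset and its ground-truth ledger from ``config``."""
    rng = np.random.default_rng(config.rng_seed)
    gens = list(config.generations)
    tuber_comps = [c for c in config.retention_prob if c != "tare_soil"]
    if not tuber_comps:
        raise ValueError("retention_prob must cover at least one tuber compartment")

    taxa: list[_Taxon] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"ASV{counter:05d}"

    # --- founder (vertical-core) taxa -------------------------------------
    for cv in config.cultivars:
        for comp in tuber_comps:
            richness = (
                config.seed_richness_flesh if comp == "flesh" else config.seed_richness_peel
            )
            p_keep = config.retention_prob.get(comp, 0.0)
            baselines = rng.normal(config.baseline_mean, config.baseline_sd, richness)
            is_null = rng.random(richness) < config.null_fraction
            retained = rng.random((richness, max(len(gens) - 1, 0))) < p_keep
            for t in range(richness):
                cells: list[tuple[str, str, str]] = [(gens[0], comp, NO_FIELD)]
                alive = True
                for gi, g in enumerate(gens[1:]):
                    alive = alive and bool(retained[t, gi])
                    if not alive:
                        break
                    if gi == 0:  # daughter generation: first field only
                        cells.append((g, comp, config.fields[0]))
                    else:
                        cells.extend((g, comp, f) for f in config.fields)
                vg_t = 0.0 if is_null[t] else config.vg
                offsets = {
                    g: (rng.normal(0.0, np.sqrt(vg_t)) if vg_t > 0 else 0.0)
                    for g in gens
                }
                denom = vg_t + config.ve
                taxa.append(
                    _Taxon(
                        taxon_id=new_id(),
                        cultivar=cv,
                        compartment=comp,
                        origin="vertical_core",
                        origin_generation=gens[0],
                        origin_field=NO_FIELD,
                        true_h2=(vg_t / denom) if denom > 0 else 0.0,
                        baseline=float(baselines[t]),
                        gen_offsets=offsets,
                        cells=cells,
                    )
                )

    # --- horizontally acquired taxa ----------------------------------------
    for cv in config.cultivars:
        peel_pools: dict[str, list[_Taxon]] = {}
        for (g, comp, fld), size in sorted(config.horizontal_pool_size.items()):
            if g not in gens or g == gens[0]:
                continue
            pool: list[_Taxon] = []
            n_new = size
            if comp == "tare_soil":
                # share part of the same field's granddaughter peel pool
                donors = peel_pools.get((g, fld), [])
                n_shared = min(
                    int(round(config.tare_soil_peel_overlap * size)), len(donors)
                )
                if n_shared:
                    idx = rng.choice(len(donors), size=n_shared, replace=False)
                    for i in sorted(idx):
                        donors[i].cells.append((g, "tare_soil", fld))
                        pool.append(donors[i])
                n_new = size - n_shared
            baselines = rng.normal(config.baseline_mean, config.baseline_sd, n_new)
            for t in range(n_new):
                tx = _Taxon(
                    taxon_id=new_id(),
                    cultivar=cv,
                    compartment=comp,
                    origin="horizontal",
                    origin_generation=g,
                    origin_field=fld,
                    true_h2=float("nan"),
                    baseline=float(baselines[t]),
                    gen_offsets={},
                    cells=[(g, comp, fld)],
                )
                taxa.append(tx)
                pool.append(tx)
            if comp == "peel":
                peel_pools[(g, fld)] = pool

    # --- sample layout -----------------------------------------------------
    samples: list[SampleMetadata] = []
    for cv in config.cultivars:
        for gi, g in enumerate(gens):
            if gi == 0:
                cells = [(c, NO_FIELD) for c in tuber_comps]
            elif gi == 1:
                cells = [(c, config.fields[0]) for c in tuber_comps]
            else:
                comps = tuber_comps + (
                    ["tare_soil"]
                    if any(
                        k[1] == "tare_soil" and k[0] == g
                        for k in config.horizontal_pool_size
                    )
                    else []
                )
                cells = [(c, f) for f in config.fields for c in comps]
            for comp, fld in cells:
                for rep in range(1, config.n_replicates + 1):
                    fld_tag = "nf" if fld == NO_FIELD else fld
                    samples.append(
                        SampleMetadata(
                            sample_id=f"{cv}.{g}.{comp}.{fld_tag}.r{rep}",
                            generation=g,
                            compartment=comp,
                            cultivar=cv,
                            field=fld,
                            replicate=rep,
                        )
                    )
    if not samples:
        raise ValueError("configuration yields zero samples")

    # --- membership index: (cultivar, generation, compartment, field) -> taxa
    members: dict[tuple[str, str, str, str], list[int]] = {}
    for ti, tx in enumerate(taxa):
        for (g, comp, fld) in tx.cells:
            members.setdefault((tx.cultivar, g, comp, fld), []).append(ti)

    counts = np.zeros((len(taxa), len(samples)), dtype=np.int64)
    baseline_arr = np.array([tx.baseline for tx in taxa])
    for sj, m in enumerate(samples):
        idx = members.get((m.cultivar, m.generation, m.compartment, m.field), [])
        if not idx:
            continue
        idx_arr = np.asarray(idx)
        loga = baseline_arr[idx_arr].copy()
        for pos, ti in enumerate(idx):
            off = taxa[ti].gen_offsets.get(m.generation, 0.0)
            if off:
                loga[pos] += off
        loga = loga + rng.normal(0.0, np.sqrt(config.ve), size=idx_arr.size)
        rel = 10.0 ** loga
        rel /= rel.sum()
        mu_log = np.log(config.library_size_mean) - 0.5 * config.library_size_shape**2
        lib = rng.lognormal(mu_log, config.library_size_shape)
        mu = rel * lib
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu / shape)
        col = rng.poisson(lam)
        if config.detection_guarantee:
            col = np.maximum(col, 1)
        counts[idx_arr, sj] = col

    table = CountTable([tx.taxon_id for tx in taxa], [m.sample_id for m in samples], counts)
    truth = SimulationTruth(
        taxa=pd.DataFrame(
            {
                "taxon_id": [tx.taxon_id for tx in taxa],
                "cultivar": [tx.cultivar for tx in taxa],
                "compartment": [tx.compartment for tx in taxa],
                "origin": [tx.origin for tx in taxa],
                "origin_generation": [tx.origin_generation for tx in taxa],
                "origin_field": [tx.origin_field for tx in taxa],
                "true_h2": [tx.true_h2 for tx in taxa],
                "retained_in": [_format_cells(tx.cells) for tx in taxa],
            }
        ),
        retention_prob=dict(config.retention_prob),
    )
    return Dataset(table, samples), truth


def truth_report(truth: SimulationTruth) -> pd.DataFrame:
    """Flat per-taxon truth table (TSV-writable)."""
    df = truth.taxa.copy()
    df["retention_prob"] = df["compartment"].map(truth.retention_prob).astype(float)
    return df


def simulate_retention_trials(
    probs: dict[str, float],
    n_contexts_per_level: int,
    n_trials: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Direct binomial retention trials for transfer-model checks.

    One row per context: ``successes ~ Binomial(n_trials, probs[level])``,
    with ``n_contexts_per_level`` contexts per factor level.
    """
    rows = []
    for level, p in probs.items():
        succ = rng.binomial(n_trials, p, size=n_contexts_per_level)
        for i, s in enumerate(succ):
            rows.append(
                {
                    "compartment": level,
                    "context": f"{level}_{i}",
                    "successes": int(s),
                    "trials": n_trials,
                }
            )
    return pd.DataFrame(rows)


def simulate_abundance_matrix(
    vg: float,
    ve: float,
    n_generations: int,
    n_replicates: int,
    n_taxa: int,
    rng: np.random.Generator,
    mu: float = -3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw transformed abundances from the one-way random-effects model.

    Returns ``(values, labels)`` where ``values`` has shape
    ``(n_taxa, n_generations * n_replicates)`` with
    value = mu + G_i + eps (G_i ~ N(0, vg) per taxon and generation,
    eps ~ N(0, ve) per observation) and ``labels`` gives each column's
    generation index.
    """
    labels = np.repeat(np.arange(n_generations), n_replicates)
    g = rng.normal(0.0, np.sqrt(vg), size=(n_taxa, n_generations))
    eps = rng.normal(0.0, np.sqrt(ve), size=(n_taxa, labels.size))
    return mu + g[:, labels] + eps, labels
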