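"""Synthetic-data generators with planted, recoverable structure.

Every analysis stage gets an input whose ground truth is known: incidence
matrices whose species are synapomorphies of the clades of a known area
cladogram (plus occurrence noise and widespread species), bivariate clouds
with or without a planted triangular constraint envelope, and covariate
tables carrying a species–area power law and nothing else.  All generators
are pure functions of their parameters and seed.

Default noise levels describe an occurrence compilation of the kind PAE is
run on: false-presence (misidentification/georeferencing) 1% per cell,
false-absence (under-sampling) 5% per cell, and 10% of species widespread
rather than endemic.  These are choices of the package, stated in the
methods notes; no canonical values exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bss import EnvelopePoints
from .incidence import COVARIATE_COLUMNS, OUTGROUP_LABEL, IncidenceMatrix
from .trees import AreaTree, edges, insert_leaf, renumber

__all__ = [
    "SyntheticTruth",
    "simulate_area_cladogram",
    "synthetic_truth",
    "simulate_incidence",
    "simulate_envelope",
    "simulate_species_area",
]


def _area_labels(n_areas):
    return tuple(f"area{i + 1:02d}" for i in range(n_areas))


def simulate_area_cladogram(n_areas: int, seed=None, labels=None,
                            outgroup_label: str = OUTGROUP_LABEL) -> AreaTree:
    """Uniform random unrooted binary tree over ``n_areas`` labels + outgroup.

    Built by sequential random-edge insertion, which visits every labelled
    topology with equal probability.
    """
    if n_areas < 3:
        raise ValueError("need at least 3 areas")
    rng = np.random.default_rng(seed)
    labels = tuple(labels) if labels is not None else _area_labels(n_areas)
    if len(labels) != n_areas:
        raise ValueError("labels length mismatch")
    og = n_areas
    hub = n_areas + 1
    adj = {0: [hub], 1: [hub], og: [hub], hub: [0, 1, og]}
    nid = n_areas + 2
    for k in range(2, n_areas):
        es = edges(adj)
        insert_leaf(adj, k, es[int(rng.integers(len(es)))], nid)
        nid += 1
    return AreaTree(labels + (outgroup_label,), renumber(adj, n_areas + 1))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    true_tree: AreaTree
    true_clades: frozenset
    false_presence_rate: float
    false_absence_rate: float
    widespread_fraction: float
    envelope: tuple | None
    sar: tuple | None
    seed: int

    def __post_init__(self):
        for name in ("false_presence_rate", "false_absence_rate",
                     "widespread_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def synthetic_truth(n_areas: int = 12, seed: int = 0,
                    false_presence_rate: float = 0.01,
                    false_absence_rate: float = 0.05,
                    widespread_fraction: float = 0.10,
                    envelope=None, sar=None) -> SyntheticTruth:
    """Draw an area cladogram and record the full planted configuration.

    ``envelope`` is (slope, intercept, noise_sd) or None; ``sar`` is
    (c, z, noise_sd) or None.  The cladogram uses the stream ``[seed, 0]``
    so the incidence stream ``[seed, 1]`` is independent of it.
    """
    tree = simulate_area_cladogram(n_areas, seed=[int(seed), 0])
    return SyntheticTruth(true_tree=tree, true_clades=tree.clades(),
                          false_presence_rate=false_presence_rate,
                          false_absence_rate=false_absence_rate,
                          widespread_fraction=widespread_fraction,
                          envelope=envelope, sar=sar, seed=int(seed))


def simulate_incidence(truth: SyntheticTruth, n_species: int,
                       seed=None) -> IncidenceMatrix:
    """Incidence matrix whose species mark the clades of the true tree.

    Each species is, with probability ``1 - widespread_fraction``, a
    synapomorphy of a uniformly chosen nontrivial clade (present exactly in
    its areas); otherwise it is widespread-random (each area an independent
    coin flip).  Cells then flip 0→1 at the false-presence rate and 1→0 at
    the false-absence rate.  Deterministic given ``truth`` (stream
    ``[truth.seed, 1]``) unless an explicit ``seed`` is passed.
    """
    if n_species < 1:
        raise ValueError("need at least 1 species")
    rng = np.random.default_rng([truth.seed, 1] if seed is None else seed)
    areas = truth.true_tree.area_labels
    n_areas = len(areas)
    pos = {a: i for i, a in enumerate(areas)}
    clades = sorted(truth.true_clades, key=lambda c: sorted(c))
    pres = np.zeros((n_species, n_areas), dtype=np.uint8)
    widespread = rng.random(n_species) < truth.widespread_fraction
    which = rng.integers(len(clades), size=n_species)
    for s in range(n_species):
        if widespread[s]:
            pres[s] = rng.integers(0, 2, size=n_areas)
        else:
            for a in clades[which[s]]:
                pres[s, pos[a]] = 1
    flip01 = rng.random(pres.shape) < truth.false_presence_rate
    flip10 = rng.random(pres.shape) < truth.false_absence_rate
    pres = np.where(pres == 0, flip01.astype(np.uint8),
                    (~flip10).astype(np.uint8))
    species = tuple(f"sp{j + 1:04d}" for j in range(n_species))
    return IncidenceMatrix(species, areas, pres)


def simulate_envelope(n: int, slope: float = 1.0, intercept: float = 0.0,
                      noise_sd: float = 0.05, constrained: bool = True,
                      seed=None) -> EnvelopePoints:
    """Bivariate cloud with (or without) a planted triangular ceiling.

    ``constrained=True``: x ~ U(0,1), y ~ U(0, max(0, slope·x + intercept))
    plus Gaussian noise, clipped at 0 — richness fills the space *below* a
    rising ceiling.  ``constrained=False``: x and y independent U(0,1), the
    null the envelope test should not reject.
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, n)
    if constrained:
        ceiling = np.maximum(0.0, slope * x + intercept)
        y = rng.uniform(0.0, ceiling)
        if noise_sd > 0:
            y = np.maximum(0.0, y + rng.normal(0.0, noise_sd, n))
    else:
        y = rng.uniform(0.0, 1.0, n)
    return EnvelopePoints(x, y)


def simulate_species_area(n_areas: int = 72, c: float = 3.0, z: float = 0.45,
                          noise_sd: float = 1.0, seed=None, area_ids=None):
    """Covariate table plus richness carrying only a species–area signal.

    Areas are log-uniform over four orders of magnitude (1e2–1e6 km²);
    richness counts follow ``c + z·ln(area) + N(0, noise_sd)``, rounded and
    floored at zero.  The altitude and climate columns are drawn
    independently of everything (respecting their physical invariants), so
    a regression should attribute signal to log(area) alone.

    Returns
    -------
    (covariates DataFrame indexed by area_id, richness Series)
    """
    if n_areas < 3:
        raise ValueError("need at least 3 areas")
    rng = np.random.default_rng(seed)
    area_ids = tuple(area_ids) if area_ids is not None else _area_labels(n_areas)
    if len(area_ids) != n_areas:
        raise ValueError("area_ids length mismatch")
    area = 10.0 ** rng.uniform(2.0, 6.0, n_areas)
    mean = c + z * np.log(area)
    resp = mean + (rng.normal(0.0, noise_sd, n_areas) if noise_sd > 0 else 0.0)
    richness = np.maximum(0, np.rint(resp)).astype(int)
    amt = rng.uniform(0.0, 28.0, n_areas)
    driest = rng.uniform(0.0, 60.0, n_areas)
    cov = pd.DataFrame(
        {
            "area": area,
            "altitude": rng.uniform(0.0, 4000.0, n_areas),
            "annual_mean_temp": amt,
            "max_temp_warmest_month": amt + rng.uniform(4.0, 12.0, n_areas),
            "min_temp_coldest_month": amt - rng.uniform(4.0, 18.0, n_areas),
            "annual_precip": rng.uniform(200.0, 3000.0, n_areas),
            "precip_driest_month": driest,
            "precip_wettest_month": driest + rng.uniform(50.0, 400.0, n_areas),
        },
        index=pd.Index(area_ids, name="area_id"),
    )[list(COVARIATE_COLUMNS)]
    return cov, pd.Series(richness, index=cov.index, name="richness")
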