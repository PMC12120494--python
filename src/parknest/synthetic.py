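"""Synthetic bird-community generator with tunable, area-driven nestedness.

Emulates the structure of an urban-park survey — by default 17 parks whose
areas span two orders of magnitude (log-uniform) and 95 species — so every
stage of the analysis can be exercised without field data.

The nestedness dial ``theta`` mixes two incidence mechanisms per species i
and site j::

    P(present) = theta * [a_j >= t_i] + (1 - theta) * q_i

where ``t_i`` is an area threshold chosen so that species i deterministically
occupies the ``k_i`` largest sites, and ``q_i = k_i / n_sites`` is the
species' mean occupancy. At ``theta = 1`` incidence is a perfectly nested
(area-threshold) pattern; at ``theta = 0`` composition is area-independent.
Occupancy decays with species rank via ``prevalence_decay`` (gamma):
``k_i = max(1, round(n_sites * ((S - i + 1) / S)**gamma))``, which makes
per-site richness span roughly an order of magnitude between the smallest
and largest parks.

Abundances for present cells are 1 + geometric (negative binomial with one
failure), overdispersed, with mean scaled by relative area. Traits are two
correlated log-normals loosely calibrated to passerine body mass (g) and
wing length (mm). Group flags (passerine/resident/guild/waterbird) are drawn
with fixed realistic proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_io import CommunityMatrix, SiteAttributes

GUILDS = ("insectivorous", "omnivorous", "granivorous", "carnivorous", "nectarivorous", "other")
GUILD_PROBS = (0.42, 0.30, 0.10, 0.08, 0.04, 0.06)
P_PASSERINE = 0.62
P_RESIDENT = 0.68
P_WATERBIRD = 0.05


@dataclass(frozen=True)
class SyntheticSpec:
    n_species: int = 95
    n_sites: int = 17
    area_range: tuple[float, float] = (2.0, 300.0)  # hectares, log-uniform
    theta: float = 0.6
    prevalence_decay: float = 1.0
    abundance_mean: float = 4.0
    trait_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.n_species < 2 or self.n_sites < 2:
            raise ValueError("need at least 2 species and 2 sites")
        if self.prevalence_decay <= 0:
            raise ValueError("prevalence_decay must be positive")
        if self.abundance_mean <= 0:
            raise ValueError("abundance_mean must be positive")
        lo, hi = self.area_range
        if lo <= 0 or hi < lo:
            raise ValueError("area_range must be positive with min <= max")
        if not -1.0 <= self.trait_corr <= 1.0:
            raise ValueError("trait_corr must be in [-1, 1]")


def _species_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def _site_ids(n: int) -> list[str]:
    return [f"P{j + 1:02d}" for j in range(n)]


def generate_community(
    spec: SyntheticSpec,
) -> tuple[CommunityMatrix, SiteAttributes, pd.DataFrame]:
    """Community matrix, site areas and species group table for one draw."""
    rng = np.random.default_rng(spec.seed)
    S, J = spec.n_species, spec.n_sites

    lo, hi = spec.area_range
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), size=J))
    area_rank = np.empty(J, dtype=int)  # 1 = largest site
    area_rank[np.argsort(-areas, kind="stable")] = np.arange(1, J + 1)

    ranks = np.arange(1, S + 1)
    occupancy = ((S - ranks + 1) / S) ** spec.prevalence_decay
    k = np.maximum(1, np.round(J * occupancy).astype(int))  # sites occupied at theta=1
    q = k / J

    nested = area_rank[None, :] <= k[:, None]  # species i occupies the k_i largest sites
    p = spec.theta * nested + (1.0 - spec.theta) * q[:, None]
    presence = rng.random((S, J)) < p

    rel = areas / areas.mean()
    lam = np.maximum(spec.abundance_mean * rel[None, :], 1e-9)
    extra = rng.negative_binomial(1, 1.0 / (1.0 + lam), size=(S, J))
    counts = np.where(presence, 1 + extra, 0)

    m = CommunityMatrix(
        pd.DataFrame(counts, index=_species_ids(S), columns=_site_ids(J))
    )
    attrs = SiteAttributes(pd.Series(areas, index=_site_ids(J), name="area"))
    groups = _generate_groups(S, rng)
    return m, attrs, groups


def _generate_groups(n_species: int, rng: np.random.Generator) -> pd.DataFrame:
    ids = _species_ids(n_species)
    return pd.DataFrame(
        {
            "is_passerine": rng.random(n_species) < P_PASSERINE,
            "is_resident": rng.random(n_species) < P_RESIDENT,
            "diet_guild": rng.choice(GUILDS, size=n_species, p=GUILD_PROBS),
            "is_waterbird": rng.random(n_species) < P_WATERBIRD,
        },
        index=pd.Index(ids, name="species_id"),
    )


def generate_traits(n_species: int, trait_corr: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Two correlated positive traits (body mass in g, wing length in mm)."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if not -1.0 <= trait_corr <= 1.0:
        raise ValueError("trait_corr must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, trait_corr], [trait_corr, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_species, method="cholesky")
    return pd.DataFrame(
        {
            "body_mass_g": np.exp(3.2 + 0.8 * z[:, 0]),
            "wing_length_mm": np.exp(4.4 + 0.35 * z[:, 1]),
        },
        index=pd.Index(_species_ids(n_species), name="species_id"),
    )


def write_fixture_set(spec: SyntheticSpec, outdir) -> dict[str, str]:
    """Materialise a standard delimited fixture set (matrix/areas/groups/traits)."""
    from pathlib import Path

    from .matrix_io import write_community_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m, attrs, groups = generate_community(spec)
    traits = generate_traits(spec.n_species, spec.trait_corr, spec.seed)
    paths = {
        "matrix": outdir / "matrix.csv",
        "areas": outdir / "areas.csv",
        "groups": outdir / "groups.csv",
        "traits": outdir / "traits.csv",
    }
    write_community_matrix(m, paths["matrix"])
    attrs.area.rename("area").rename_axis("site_id").to_csv(paths["areas"])
    groups.to_csv(paths["groups"])
    traits.to_csv(paths["traits"])
    return {k: str(v) for k, v in paths.items()}
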