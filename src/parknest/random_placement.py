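"""Coleman's random placement model — the passive-sampling test.

If individuals simply scatter over sites in proportion to site area, larger
sites collect more species without any ecological structure. With pooled
abundance ``n_i`` for species i and relative area ``a_j = A_j / sum(A)``,
the probability that species i misses site j is ``(1 - a_j)**n_i``, so

    E_j  = S - sum_i (1 - a_j)**n_i
    Var_j = sum_i (1 - a_j)**n_i * (1 - (1 - a_j)**n_i)

The passive-sampling hypothesis is rejected when more than one third of the
sites have observed richness outside one standard deviation of the expected
curve; sites exactly on the boundary count as within.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix_io import CommunityMatrix, SiteAttributes

logger = logging.getLogger("parknest")

REJECTION_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class RandomPlacementResult:
    per_site: pd.DataFrame  # site_id, area, relative_area, expected, sd, observed, within_1sd
    fraction_outside: float
    passive_sampling_rejected: bool


def coleman_curve(abundances: pd.Series, areas: SiteAttributes) -> pd.DataFrame:
    """Expected richness and SD per site under random placement.

    ``abundances`` are pooled per-species totals; species with zero total are
    dropped with a warning.
    """
    x = pd.Series(abundances, dtype=float)
    if (x == 0).any():
        logger.warning(
            "dropping %d species with zero pooled abundance", int((x == 0).sum())
        )
        x = x[x > 0]
    if x.empty:
        raise ValueError("no species with positive abundance")
    a = areas.relative_area().to_numpy()
    n = x.to_numpy()
    miss = (1.0 - a[:, None]) ** n[None, :]  # P(species i absent from site j)
    expected = len(n) - miss.sum(axis=1)
    var = (miss * (1.0 - miss)).sum(axis=1)
    return pd.DataFrame(
        {
            "area": areas.area.to_numpy(),
            "relative_area": a,
            "expected": expected,
            "sd": np.sqrt(var),
        },
        index=areas.area.index,
    )


def passive_sampling_test(m: CommunityMatrix, areas: SiteAttributes) -> RandomPlacementResult:
    """Compare observed per-site richness to the random placement envelope."""
    area = SiteAttributes(areas.aligned_to(m.site_ids))
    curve = coleman_curve(m.species_totals(), area)
    observed = m.site_richness()
    curve["observed"] = observed
    curve["within_1sd"] = (observed >= curve["expected"] - curve["sd"]) & (
        observed <= curve["expected"] + curve["sd"]
    )
    fraction_outside = float((~curve["within_1sd"]).mean())
    return RandomPlacementResult(
        per_site=curve.rename_axis("site_id"),
        fraction_outside=fraction_outside,
        passive_sampling_rejected=fraction_outside > REJECTION_FRACTION,
    )


def simulate_random_placement(
    abundances: pd.Series, areas: SiteAttributes, seed: int
) -> np.ndarray:
    """Place each species' individuals multinomially with cell probability a_j.

    Returns a species x sites count matrix; used for self-consistency checks
    (data generated by the model should rarely reject it).
    """
    rng = np.random.default_rng(seed)
    a = areas.relative_area().to_numpy()
    out = np.vstack(
        [rng.multinomial(int(n), a) for n in pd.Series(abundances).to_numpy()]
    )
    return out
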