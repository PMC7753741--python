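"""Per-trait parallelism calls from paired field / common-garden model fits.

A trait is called parallel (genetically determined) when the ecotype
effect is significant and the ecotype x region interaction is not, in
both the field and the common-garden dataset; a significant interaction
in both datasets marks genetically determined non-parallelism; a signal
present in the field but absent in the garden marks plasticity.  The
effect-size plane (eta2 of the interaction on x, eta2 of ecotype on y)
locates each trait relative to the parallel/non-parallel diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pheno import ALPHA, TraitModelFit

logger = logging.getLogger("parallodrome")

CATEGORIES = ("parallel_genetic", "plastic", "nonparallel_genetic",
              "nonparallel_plastic", "none")


@dataclass
class ParallelismCall:
    trait: str
    call: str
    evidence: dict                  # field/garden p-values and eta2 values
    above_diagonal_field: bool      # eta2_ecotype > eta2_interaction (strict)
    above_diagonal_garden: bool


def classify_trait(field: TraitModelFit, garden: TraitModelFit,
                   alpha: float = ALPHA) -> ParallelismCall:
    """Apply the parallelism decision rules to one trait.

    In order of precedence: (1) interaction significant in both datasets
    -> nonparallel_genetic (a significant ecotype x region interaction is
    indicative of non-parallelism regardless of the ecotype main effect);
    (2) ecotype significant and interaction non-significant in both
    datasets -> parallel_genetic; (3) ecotype or interaction significant
    in the field but neither in the garden -> plastic, sub-typed
    nonparallel_plastic when the field signal was the interaction;
    (4) otherwise none.
    """
    if field.trait != garden.trait:
        raise ValueError(
            f"mismatched traits: field {field.trait!r} vs garden {garden.trait!r}"
        )
    f_eco = field.p_ecotype <= alpha
    f_int = field.p_interaction <= alpha
    g_eco = garden.p_ecotype <= alpha
    g_int = garden.p_interaction <= alpha
    if f_int and g_int:
        call = "nonparallel_genetic"
    elif f_eco and not f_int and g_eco and not g_int:
        call = "parallel_genetic"
    elif (f_eco or f_int) and not g_eco and not g_int:
        call = "nonparallel_plastic" if f_int else "plastic"
    else:
        call = "none"
    evidence = {
        "field": {"p_ecotype": field.p_ecotype, "p_region": field.p_region,
                  "p_interaction": field.p_interaction,
                  "eta2_ecotype": field.eta2_ecotype,
                  "eta2_interaction": field.eta2_interaction},
        "garden": {"p_ecotype": garden.p_ecotype, "p_region": garden.p_region,
                   "p_interaction": garden.p_interaction,
                   "eta2_ecotype": garden.eta2_ecotype,
                   "eta2_interaction": garden.eta2_interaction},
        "alpha": alpha,
    }
    return ParallelismCall(
        trait=field.trait,
        call=call,
        evidence=evidence,
        above_diagonal_field=field.eta2_ecotype > field.eta2_interaction,
        above_diagonal_garden=garden.eta2_ecotype > garden.eta2_interaction,
    )


def _bh_adjust(fits: dict) -> dict:
    """Benjamini-Hochberg adjustment of the ecotype and interaction
    p-values across traits (per dataset, per test family)."""
    from dataclasses import replace

    from statsmodels.stats.multitest import multipletests

    traits = list(fits)
    out = dict(fits)
    for attr in ("p_ecotype", "p_region", "p_interaction"):
        adj = multipletests([getattr(fits[t], attr) for t in traits],
                            method="fdr_bh")[1]
        for t, p in zip(traits, adj):
            out[t] = replace(out[t], **{attr: float(p)})
    return out


def classify_all(field_fits: dict, garden_fits: dict,
                 alpha: float = ALPHA, adjust: bool = False):
    """Classify every shared trait; returns (table, category counts).

    Traits present in only one dataset are excluded with a warning.  The
    table carries, per dataset, the scatter coordinates of the effect-size
    plane (x = eta2 of the interaction, y = eta2 of ecotype) and the
    above-diagonal flags.  ``adjust`` applies a Benjamini-Hochberg
    correction across traits (off by default: the decision rules assume
    conventional per-test significance).
    """
    if adjust:
        field_fits = _bh_adjust(field_fits)
        garden_fits = _bh_adjust(garden_fits)
    shared = [t for t in field_fits if t in garden_fits]
    only = sorted(set(field_fits) ^ set(garden_fits))
    if only:
        logger.warning("classify_all: trait(s) in one dataset only, excluded: %s",
                       only)
    rows = []
    for t in shared:
        call = classify_trait(field_fits[t], garden_fits[t], alpha=alpha)
        f, g = field_fits[t], garden_fits[t]
        rows.append({
            "trait": t, "call": call.call,
            "field_p_ecotype": f.p_ecotype, "field_p_interaction": f.p_interaction,
            "garden_p_ecotype": g.p_ecotype, "garden_p_interaction": g.p_interaction,
            "field_x_eta2_interaction": f.eta2_interaction,
            "field_y_eta2_ecotype": f.eta2_ecotype,
            "garden_x_eta2_interaction": g.eta2_interaction,
            "garden_y_eta2_ecotype": g.eta2_ecotype,
            "above_diagonal_field": call.above_diagonal_field,
            "above_diagonal_garden": call.above_diagonal_garden,
        })
    table = pd.DataFrame(rows)
    counts = {c: 0 for c in CATEGORIES}
    if len(table):
        counts.update(table["call"].value_counts().to_dict())
    return table, counts


def scatter_coordinates(table: pd.DataFrame, dataset: str) -> pd.DataFrame:
    """Effect-size scatter (one row per trait) for one dataset."""
    if dataset not in ("field", "garden"):
        raise ValueError("dataset must be field or garden")
    return table[[
        "trait", "call", f"{dataset}_x_eta2_interaction",
        f"{dataset}_y_eta2_ecotype", f"above_diagonal_{dataset}",
    ]].rename(columns={
        f"{dataset}_x_eta2_interaction": "eta2_interaction",
        f"{dataset}_y_eta2_ecotype": "eta2_ecotype",
        f"above_diagonal_{dataset}": "above_diagonal",
    })
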