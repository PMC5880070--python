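"""De-regression of PTAs into independent pseudo-phenotypes.

A bull's published PTA blends its own progeny information with the parent
average (PA) and is shrunken toward it.  Using either pseudo-phenotype
directly in marker regression double-counts family information, so the PA
contribution and the shrinkage are removed following the two-equation
mixed-model algebra of Garrick, Taylor & Fernando (2009).

With ``lam = (1 - h2) / h2``, ``alpha = 1 / (0.5 - rel_pa)`` and
``delta = (0.5 - rel_pa) / (1 - rel)``, the information contents (records
equivalents) of the PA and of the bull's own data solve the 2x2 system

    u       = 0.5 * lam * (alpha + sqrt(alpha**2 + 16 / delta))
    zpz_pa  = u - 4 * lam
    zpz_own = delta * u - 2 * lam

and the de-regressed PTA is the bull's own right-hand side re-solved
without the PA link::

    y_own = -2 * lam * pa + (zpz_own + 2 * lam) * pta
    dpta  = y_own / zpz_own
    rel_dpta = zpz_own / (zpz_own + lam)

The association weight is ``w = (1 - h2) / ((c + (1 - r) / r) * h2)`` with
``r = rel_dpta`` and the c parameter (default 0.5) controlling how much
emphasis low-reliability records receive.

All algebra is scale-equivariant: it applies unchanged on the PTA scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: per-trait heritability proxies entering the weights: low for the
#: categorical calving traits, moderate for type, high for gestation length
DEFAULT_H2 = {"DCD": 0.1, "MCD": 0.1, "GL": 0.5, "STAT": 0.4, "STR": 0.4, "RW": 0.4}
DEFAULT_REL_PA = 0.2


@dataclass
class DeregressedRecord:
    bull: str
    trait: str
    dpta: float
    w: float
    rel_dpta: float


def estimate_parent_average(sire_pta=None, mgs_pta=None, ayb_pta=None) -> float:
    """Parent average from whichever of the three fallback patterns applies.

    In order of preference: 0.5*sire + 0.25*MGS + 0.25*AYB (all present);
    0.5*sire + 0.5*AYB (MGS absent); 0.25*MGS + 0.75*AYB (sire absent),
    where AYB is the bull's birth-year cohort mean PTA.
    """
    def ok(x):
        return x is not None and not (isinstance(x, float) and np.isnan(x))

    if ok(sire_pta) and ok(mgs_pta) and ok(ayb_pta):
        return 0.5 * sire_pta + 0.25 * mgs_pta + 0.25 * ayb_pta
    if ok(sire_pta) and ok(ayb_pta):
        return 0.5 * sire_pta + 0.5 * ayb_pta
    if ok(mgs_pta) and ok(ayb_pta):
        return 0.25 * mgs_pta + 0.75 * ayb_pta
    raise ValueError(
        "parent average not estimable: need (sire, MGS, AYB), (sire, AYB) "
        "or (MGS, AYB) PTAs"
    )


def deregress_one(pta, rel, pa, rel_pa, h2, c: float = 0.5):
    """De-regress a single PTA; returns ``(dpta, w, rel_dpta)``.

    Returns ``None`` when the record carries no own information beyond the
    parent average (non-positive own records equivalent).
    """
    if not 0.0 < rel < 1.0:
        raise ValueError(f"reliability must lie strictly in (0,1), got {rel}")
    rel_pa = min(float(rel_pa), 0.4999)
    lam = (1.0 - h2) / h2
    alpha = 1.0 / (0.5 - rel_pa)
    delta = (0.5 - rel_pa) / (1.0 - rel)
    u = 0.5 * lam * (alpha + np.sqrt(alpha * alpha + 16.0 / delta))
    zpz_own = delta * u - 2.0 * lam
    if zpz_own <= 0.0:
        return None
    y_own = -2.0 * lam * pa + (zpz_own + 2.0 * lam) * pta
    dpta = y_own / zpz_own
    rel_dpta = zpz_own / (zpz_own + lam)
    w = (1.0 - h2) / ((c + (1.0 - rel_dpta) / rel_dpta) * h2)
    return float(dpta), float(w), float(rel_dpta)


def deregress(
    records: pd.DataFrame,
    c: float = 0.5,
    h2: dict | None = None,
    default_rel_pa: float = DEFAULT_REL_PA,
) -> pd.DataFrame:
    """De-regress an evaluation table; appends ``dpta``, ``w``, ``rel_dpta``.

    ``records`` follows the evaluation dialect (bull, trait, pta, rel, and
    either an explicit ``pa`` or the sire/MGS/AYB PTAs for the fallback
    formulas).  Records with no own information are dropped with a logged
    reason.
    """
    h2 = {**DEFAULT_H2, **(h2 or {})}
    out = []
    dropped = 0
    for row in records.itertuples(index=False):
        d = row._asdict()
        pa = d.get("pa")
        if pa is None or (isinstance(pa, float) and np.isnan(pa)):
            try:
                pa = estimate_parent_average(
                    d.get("sire_pta"), d.get("mgs_pta"), d.get("ayb_pta")
                )
            except ValueError as err:
                raise ValueError(f"bull {d['bull']} trait {d['trait']}: {err}") from err
        rel_pa = d.get("rel_pa")
        if rel_pa is None or (isinstance(rel_pa, float) and np.isnan(rel_pa)):
            rel_pa = default_rel_pa
        trait = d["trait"]
        if trait not in h2:
            raise KeyError(f"no heritability proxy configured for trait {trait!r}")
        res = deregress_one(d["pta"], d["rel"], pa, rel_pa, h2[trait], c=c)
        if res is None:
            dropped += 1
            log.warning(
                "bull %s trait %s: no own information beyond parent average; dropped",
                d["bull"], trait,
            )
            continue
        d["pa"], d["rel_pa"] = pa, rel_pa
        d["dpta"], d["w"], d["rel_dpta"] = res
        out.append(d)
    if dropped:
        log.info("de-regression dropped %d record(s) without own information", dropped)
    return pd.DataFrame(out)


def filter_records(
    records: pd.DataFrame,
    min_rel: float = 0.2,
    require_all_traits: bool = True,
    traits=None,
    strict: bool = True,
) -> pd.DataFrame:
    """Keep records with dPTA reliability above ``min_rel`` and, optionally,
    only bulls that retain pseudo-phenotypes in every trait (avoids an
    animal-trait confounding when all traits are analysed jointly)."""
    op = np.greater if strict else np.greater_equal
    kept = records[op(records["rel_dpta"], min_rel)]
    if require_all_traits:
        traits = set(traits) if traits is not None else set(records["trait"].unique())
        counts = kept.groupby("bull")["trait"].nunique()
        full = counts[counts == len(traits)].index
        kept = kept[kept["bull"].isin(full)]
    if kept.empty:
        raise ValueError(
            "no records survive filtering; review the min_rel threshold "
            f"(min_rel={min_rel}) and trait completeness requirement"
        )
    return kept.reset_index(drop=True)
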