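"""Ligand-observed CPMG fragment-screen hit calling.

In a CPMG relaxation-filtered experiment, a small molecule that binds the
protein relaxes faster and its signal is attenuated relative to a
protein-free reference. The attenuation ratio rho = I(with protein) / I(reference)
is the screening observable: rho <= tau calls a binder. Adding a site-specific
competitor (m7-GTP for the mRNA cap site) and re-recording assigns competed
binders to that site: a recovery of the ratio by at least ``recovery_delta``
marks displacement from the cap site.

Thresholds are explicit parameters; the defaults (tau = 0.8, i.e. >= 20%
attenuation, recovery_delta = 0.15) reflect common practice for 600 ms CPMG
filters. Input tables are one row per fragment (pre-aggregated over
resonances; raw spectra processing is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import logging

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.8
DEFAULT_RECOVERY_DELTA = 0.15


class CompetitionClass(str, Enum):
    SITE1_COMPETED = "site1_competed"
    NOT_COMPETED = "not_competed"
    NOT_TESTED = "not_tested"


@dataclass(frozen=True)
class ScreenRecord:
    """Per-fragment CPMG intensities: reference, with protein, post-competitor."""

    fragment_id: str
    cocktail_id: str
    i_ref: float
    i_protein: float
    i_competitor: float | None = None

    def __post_init__(self) -> None:
        for label, v in (("i_ref", self.i_ref), ("i_protein", self.i_protein)):
            if not (v >= 0) or v != v:
                raise ValueError(f"{self.fragment_id}: {label} must be finite and >= 0")
        if self.i_competitor is not None and not (self.i_competitor >= 0):
            raise ValueError(f"{self.fragment_id}: i_competitor must be >= 0")


@dataclass
class HitCall:
    fragment_id: str
    rho: float
    rho_comp: float | None
    is_binder: bool
    competition_class: CompetitionClass = CompetitionClass.NOT_TESTED


def attenuation_ratio(i_signal: float, i_ref: float) -> float:
    """Signal intensity scaled to the protein-free reference intensity."""
    if i_ref <= 0:
        raise ValueError(f"reference intensity must be positive, got {i_ref}")
    return i_signal / i_ref


def classify_competition(
    call: HitCall, recovery_delta: float = DEFAULT_RECOVERY_DELTA
) -> CompetitionClass:
    """Assign a binder to the cap site if its ratio recovers after competitor.

    Signal recovery toward 1 on m7-GTP addition means the fragment was
    displaced from the cap-binding site.
    """
    if not call.is_binder:
        raise ValueError(f"{call.fragment_id}: competition is only defined for binders")
    if call.rho_comp is None:
        logger.info("%s: no competitor intensity recorded", call.fragment_id)
        return CompetitionClass.NOT_TESTED
    if call.rho_comp - call.rho >= recovery_delta:
        return CompetitionClass.SITE1_COMPETED
    return CompetitionClass.NOT_COMPETED


def call_hits(
    records: Sequence[ScreenRecord],
    tau: float = DEFAULT_TAU,
    recovery_delta: float = DEFAULT_RECOVERY_DELTA,
) -> tuple[list[HitCall], dict]:
    """Call binders at attenuation threshold tau and summarise the screen.

    A fragment is a binder iff rho <= tau (boundary counts as a hit). The
    summary reports the library size, hit count and hit rate in percent
    rounded to one decimal.
    """
    if not records:
        raise ValueError("no screen records supplied")
    if not (0 < tau < 1):
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    seen: set[str] = set()
    calls: list[HitCall] = []
    for rec in records:
        if rec.fragment_id in seen:
            raise ValueError(f"duplicate fragment_id {rec.fragment_id!r}")
        seen.add(rec.fragment_id)
        rho = attenuation_ratio(rec.i_protein, rec.i_ref)
        rho_comp = (
            attenuation_ratio(rec.i_competitor, rec.i_ref)
            if rec.i_competitor is not None
            else None
        )
        call = HitCall(
            fragment_id=rec.fragment_id,
            rho=rho,
            rho_comp=rho_comp,
            is_binder=rho <= tau,
        )
        if call.is_binder:
            call.competition_class = classify_competition(call, recovery_delta)
        calls.append(call)
    n_hits = sum(c.is_binder for c in calls)
    summary = {
        "n_library": len(calls),
        "n_hits": n_hits,
        "hit_rate_percent": round(100.0 * n_hits / len(calls), 1),
        "tau": tau,
        "n_site1_competed": sum(
            c.competition_class is CompetitionClass.SITE1_COMPETED for c in calls
        ),
    }
    return calls, summary


# ---------------------------------------------------------------------------
# Table IO


def read_screen_csv(path) -> list[ScreenRecord]:
    """Read a screen table: fragment_id, cocktail_id, i_ref, i_protein[, i_competitor]."""
    df = pd.read_csv(path)
    required = {"fragment_id", "cocktail_id", "i_ref", "i_protein"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        comp = getattr(row, "i_competitor", None)
        if comp is not None and pd.isna(comp):
            comp = None
        records.append(
            ScreenRecord(
                fragment_id=str(row.fragment_id),
                cocktail_id=str(row.cocktail_id),
                i_ref=float(row.i_ref),
                i_protein=float(row.i_protein),
                i_competitor=None if comp is None else float(comp),
            )
        )
    return records


def write_screen_csv(records: Sequence[ScreenRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "fragment_id": r.fragment_id,
                "cocktail_id": r.cocktail_id,
                "i_ref": r.i_ref,
                "i_protein": r.i_protein,
                "i_competitor": r.i_competitor,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def calls_to_frame(calls: Sequence[HitCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fragment_id": c.fragment_id,
                "rho": c.rho,
                "rho_comp": c.rho_comp,
                "is_binder": c.is_binder,
                "competition_class": c.competition_class.value,
            }
            for c in calls
        ]
    )
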