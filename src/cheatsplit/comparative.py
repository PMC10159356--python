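"""Per-realm comparative summaries: do viral realms whose genera produce
defective interfering (DI) genomes also contain more multipartite genera?

Virus realms are treated as independent origins of viruses, so the unit of
comparison is the realm and the statistic is the pair of fractions
(genera with known DI production, genera containing multipartite species).
With a handful of realms no significance test is meaningful; both the rank
(Spearman) and linear (Pearson) correlation across realms are reported as
descriptive measures of association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenusRecord",
    "RealmSummary",
    "load_genus_table",
    "summarise_realms",
    "association",
]

logger = logging.getLogger(__name__)

GENUS_CSV_COLUMNS = ["genus", "realm", "has_di", "is_multipartite", "max_segments"]


@dataclass(frozen=True)
class GenusRecord:
    genus: str
    realm: Optional[str]
    has_di: bool
    is_multipartite: bool
    max_segments: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_segments is not None:
            if self.max_segments < 1:
                raise ValueError("max_segments must be >= 1")
            if self.is_multipartite != (self.max_segments > 1):
                raise ValueError(
                    f"{self.genus}: is_multipartite inconsistent with "
                    f"max_segments={self.max_segments}"
                )


@dataclass(frozen=True)
class RealmSummary:
    realm: str
    n_genera: int
    fraction_di: float
    fraction_multipartite: float


def load_genus_table(path) -> list[GenusRecord]:
    """Read a genus-level CSV (columns ``genus, realm, has_di,
    is_multipartite[, max_segments]``)."""
    df = pd.read_csv(path)
    missing = {"genus", "realm", "has_di", "is_multipartite"} - set(df.columns)
    if missing:
        raise ValueError(f"genus CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        realm = row["realm"]
        seg = row.get("max_segments")
        records.append(
            GenusRecord(
                genus=str(row["genus"]),
                realm=None if pd.isna(realm) else str(realm),
                has_di=bool(row["has_di"]),
                is_multipartite=bool(row["is_multipartite"]),
                max_segments=None if pd.isna(seg) else int(seg),
            )
        )
    return records


def summarise_realms(records: list[GenusRecord]) -> list[RealmSummary]:
    """Per-realm genus counts and DI / multipartite fractions.

    Genera without an assigned realm are excluded (with a logged count);
    duplicated genus names are an integrity error.
    """
    if not records:
        raise ValueError("no genus records supplied")
    names = [r.genus for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate genus: {dupes}")
    unassigned = sum(1 for r in records if r.realm is None)
    if unassigned:
        logger.info("excluded %d genera with no assigned realm", unassigned)
    assigned = [r for r in records if r.realm is not None]
    if not assigned:
        raise ValueError("no genus records with an assigned realm")
    summaries = []
    for realm in sorted({r.realm for r in assigned}):
        grp = [r for r in assigned if r.realm == realm]
        n = len(grp)
        summaries.append(
            RealmSummary(
                realm=realm,
                n_genera=n,
                fraction_di=sum(r.has_di for r in grp) / n,
                fraction_multipartite=sum(r.is_multipartite for r in grp) / n,
            )
        )
    return summaries


def association(summaries: list[RealmSummary]) -> dict:
    """Spearman and Pearson correlations of fraction_multipartite against
    fraction_di across realms.  A coefficient is ``nan`` with a degenerate
    flag when one fraction has zero variance.  No p-values: the number of
    realms is tiny by design."""
    if len(summaries) < 3:
        raise ValueError("insufficient realms: association needs >= 3")
    x = np.array([s.fraction_di for s in summaries])
    y = np.array([s.fraction_multipartite for s in summaries])
    degenerate = bool(np.ptp(x) == 0 or np.ptp(y) == 0)
    if degenerate:
        spearman = pearson = float("nan")
    else:
        spearman = float(stats.spearmanr(x, y).statistic)
        pearson = float(stats.pearsonr(x, y).statistic)
    return {"spearman": spearman, "pearson": pearson, "degenerate": degenerate}


def summaries_to_frame(summaries: list[RealmSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "realm": [s.realm for s in summaries],
            "n_genera": [s.n_genera for s in summaries],
            "fraction_di": [s.fraction_di for s in summaries],
            "fraction_multipartite": [s.fraction_multipartite for s in summaries],
        }
    )
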