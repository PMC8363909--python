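"""Rule-based protein catalogues from differential fraction proteomics.

Two catalogues are derived from comparing crude (size-selected), LPP
(lipoprotein-density) and EV (vesicle-density) extracts:

* **putative non-EV-associated proteins** — co-elute with particles during
  size separation (detected in the crude extract) but band at lipoprotein
  rather than vesicle density (significantly enriched toward the LPP
  extract);
* **putative EV-corona candidates** — detected in the crude extract, band
  at vesicle density (significantly enriched toward the EV extract), and
  annotated as secreted proteins yet consistently identified in EV
  extracts — soluble proteins adsorbed at the vesicle surface.

Significance comes from the permutation-FDR q-values of
:mod:`plasmafrac.proteostats`; direction from the sign of the group-mean
difference.  Corona candidate abundance can additionally be correlated with
blood-plasma concentration (Spearman, exact enumeration p for small n).
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_catalogue",
    "select_non_ev_associated",
    "select_corona_candidates",
    "crude_presence",
    "corona_concentration_correlation",
    "spearman_exact",
]


def crude_presence(crude_matrix: pd.DataFrame, min_valid_fraction: float = 2.0 / 3.0) -> set[str]:
    """Proteins detected (non-missing) in >= ``min_valid_fraction`` of crude replicates.

    The same 66.67 % valid-value rule used by the differential filter defines
    "identified in the crude extract".
    """
    frac = crude_matrix.notna().sum(axis=1) / crude_matrix.shape[1]
    return set(crude_matrix.index[frac >= min_valid_fraction - 1e-9])


def build_catalogue(
    crude_present: Iterable[str],
    diff_lpp_vs_ev: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    alpha: float = 0.05,
    ev_valid_fraction: pd.Series | None = None,
    min_valid_fraction: float = 2.0 / 3.0,
) -> pd.DataFrame:
    """Classify every tested protein.

    Parameters
    ----------
    crude_present:
        Ids of proteins identified in the crude extract.
    diff_lpp_vs_ev:
        Result of the LPP-vs-EV differential test (columns ``diff``, ``q``),
        with ``diff`` > 0 meaning enriched in the LPP extract.  The EV-vs-LPP
        direction is the sign flip, so one table serves both criteria.
    annotations:
        Optional table indexed by protein id with a ``secreted`` column
        (0/1) and optionally ``plasma_concentration``.  Proteins missing
        from the table are treated as not secreted (logged).
    ev_valid_fraction:
        Optional per-protein fraction of EV replicates with a valid
        (non-imputed) value, used to enforce "consistently identified in EV
        extracts"; when absent the criterion reduces to the q/direction and
        secretion checks.

    Returns
    -------
    DataFrame indexed by protein with boolean criteria columns and a
    ``category`` in {non_EV_associated, corona_candidate, unclassified}.
    """
    crude_present = set(crude_present)
    proteins = diff_lpp_vs_ev.index
    if annotations is not None:
        unknown = proteins.difference(annotations.index)
        if len(unknown) > 0:
            warnings.warn(
                f"{len(unknown)} tested proteins lack annotation; treated as not secreted"
            )
        secreted = pd.Series(
            [bool(annotations["secreted"].get(p, 0)) for p in proteins], index=proteins
        )
    else:
        secreted = pd.Series(False, index=proteins)

    in_crude = pd.Series([p in crude_present for p in proteins], index=proteins)
    q = diff_lpp_vs_ev["q"]
    diff = diff_lpp_vs_ev["diff"]
    lpp_enriched = (q < alpha) & (diff > 0)
    ev_enriched = (q < alpha) & (diff < 0)
    if ev_valid_fraction is not None:
        consistent_ev = ev_valid_fraction.reindex(proteins).fillna(0.0) >= min_valid_fraction - 1e-9
    else:
        consistent_ev = pd.Series(True, index=proteins)

    non_ev = in_crude & lpp_enriched
    corona = in_crude & ev_enriched & secreted & consistent_ev
    category = pd.Series("unclassified", index=proteins)
    category[non_ev] = "non_EV_associated"
    category[corona] = "corona_candidate"
    return pd.DataFrame(
        {
            "in_crude": in_crude,
            "q_lpp_vs_ev": q,
            "lpp_enriched": lpp_enriched,
            "ev_enriched": ev_enriched,
            "secreted": secreted,
            "consistent_in_ev": consistent_ev,
            "category": category,
        }
    )


def select_non_ev_associated(
    crude_present: Iterable[str], diff_lpp_vs_ev: pd.DataFrame, alpha: float = 0.05
) -> pd.Index:
    """Proteins in the crude extract that are significantly LPP-enriched.

    An empty crude set yields an empty catalogue with a warning.
    """
    crude_present = set(crude_present)
    if not crude_present:
        warnings.warn("empty crude presence set; catalogue is empty")
        return pd.Index([], dtype=object)
    cat = build_catalogue(crude_present, diff_lpp_vs_ev, alpha=alpha)
    return cat.index[cat["category"] == "non_EV_associated"]


def select_corona_candidates(
    crude_present: Iterable[str],
    diff_ev_vs_lpp: pd.DataFrame,
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    ev_valid_fraction: pd.Series | None = None,
    min_valid_fraction: float = 2.0 / 3.0,
) -> pd.Index:
    """Secreted, crude-present proteins significantly enriched in EV extracts.

    ``diff_ev_vs_lpp`` has ``diff`` > 0 meaning enriched in the EV extract;
    it is sign-flipped into the shared LPP-vs-EV convention internally.
    """
    flipped = diff_ev_vs_lpp.copy()
    flipped["diff"] = -flipped["diff"]
    cat = build_catalogue(
        crude_present, flipped, annotations=annotations, alpha=alpha,
        ev_valid_fraction=ev_valid_fraction, min_valid_fraction=min_valid_fraction,
    )
    return cat.index[cat["category"] == "corona_candidate"]


# ---------------------------------------------------------------------------
# corona-abundance vs plasma-concentration correlation
# ---------------------------------------------------------------------------

def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)


def spearman_exact(x, y, enumeration_limit: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p for small n.

    For n <= ``enumeration_limit`` the two-sided p is the fraction of all n!
    orderings of one variable whose |rho| reaches the observed value; ties
    are handled by average ranks.  Larger samples use the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    n = x.size
    if n <= enumeration_limit:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
        if denom == 0:
            return rho, 1.0
        count = 0
        total = 0
        # chunked enumeration of all orderings of the y-ranks
        chunk: list[tuple[int, ...]] = []
        for perm in permutations(range(n)):
            chunk.append(perm)
            if len(chunk) == 40320:  # 8! rows per block
                count, total = _accumulate(chunk, rxc, ryc, denom, rho, count, total)
                chunk = []
        if chunk:
            count, total = _accumulate(chunk, rxc, ryc, denom, rho, count, total)
        return rho, count / total
    # t approximation
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, min(p, 1.0)


def _accumulate(chunk, rxc, ryc, denom, rho, count, total):
    perm_arr = np.asarray(chunk, dtype=np.int64)
    rhos = (ryc[perm_arr] @ rxc) / denom
    count += int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))
    total += perm_arr.shape[0]
    return count, total


def corona_concentration_correlation(
    mean_intensities: pd.Series, annotations: pd.DataFrame
) -> tuple[float, float]:
    """Spearman correlation of corona-protein abundance with plasma concentration.

    ``mean_intensities`` holds per-protein mean EV-extract intensities for the
    corona candidates; concentrations come from the annotation table.  At
    least 5 proteins with known concentration are required.
    """
    conc = annotations["plasma_concentration"].reindex(mean_intensities.index)
    keep = conc.notna() & mean_intensities.notna()
    if int(keep.sum()) < 5:
        raise ValueError("need at least 5 corona proteins with known concentrations")
    return spearman_exact(mean_intensities[keep].to_numpy(), conc[keep].to_numpy())
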