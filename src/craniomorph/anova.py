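"""Procrustes ANOVA for object symmetry.

Two-factor mixed-effect decomposition of Procrustes sums of squares
into Individual (symmetric variation among specimens), Side
(directional asymmetry), Individual x Side (fluctuating asymmetry) and
Error (replicate digitization disagreement) strata.  F ratios follow
the mixed-model convention for this design: Individual and Side are
tested over the interaction, the interaction over measurement error.

Degrees of freedom use the standard object-symmetry bookkeeping for
3D configurations with ``p`` bilateral pairs and ``q`` midline
landmarks: the shape space (dimension ``3k - 7``) splits into a
symmetric subspace of dimension ``3p + 2q - 4`` and an asymmetric
subspace of dimension ``3p + q - 3``; Individual has ``(n-1)``
times the symmetric dimension, Side the asymmetric dimension,
the interaction ``(n-1)`` times the asymmetric dimension, and Error
``n (r-1) (3k - 7)``.  Printed tables whose df follow another
convention can still be reproduced arithmetically through
:func:`anova_table_from_ss`, which accepts the SS and df as given.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gpa import DEFAULT_SEED, ProcrustesFit, decompose_symmetry, gpa
from .io import LandmarkDataset, LandmarkScheme

EFFECTS = ("Individual", "Side", "Individual x Side", "Error")


class AnovaError(ValueError):
    pass


@dataclass
class AnovaTable:
    """Effect table with SS, MS, df, F and p columns."""

    frame: pd.DataFrame
    permutation_p: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, effect: str) -> pd.Series:
        return self.frame.loc[effect]

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


def symmetry_dimensions(n_pairs: int, n_midline: int) -> tuple[int, int]:
    """(symmetric, asymmetric) shape-space dimensions for 3D object symmetry."""
    d_sym = 3 * n_pairs + 2 * n_midline - 4
    d_asym = 3 * n_pairs + n_midline - 3
    return d_sym, d_asym


def anova_table_from_ss(
    ss_by_effect: dict[str, float],
    df_by_effect: dict[str, int],
) -> AnovaTable:
    """Build the effect table from given SS and df.

    MS = SS/df; F(Individual) = MS_Individual / MS_Interaction,
    F(Side) = MS_Side / MS_Interaction, and — when an Error stratum is
    present — F(Interaction) = MS_Interaction / MS_Error.  p-values come
    from the F distribution with the corresponding df pair.
    """
    for eff, ss in ss_by_effect.items():
        if ss < 0:
            raise AnovaError(f"negative SS for {eff}")
        if eff not in df_by_effect:
            raise AnovaError(f"missing df for effect {eff}")
        if df_by_effect[eff] <= 0:
            raise AnovaError(f"df for {eff} must be positive")
    has_int = "Individual x Side" in ss_by_effect
    if ("Individual" in ss_by_effect or "Side" in ss_by_effect) and not has_int:
        raise AnovaError("interaction stratum required to form F for main effects")
    ms = {e: ss_by_effect[e] / df_by_effect[e] for e in ss_by_effect}
    rows = []
    for eff in EFFECTS:
        if eff not in ss_by_effect:
            continue
        f = p = np.nan
        if eff in ("Individual", "Side"):
            denom, ddf = ms["Individual x Side"], df_by_effect["Individual x Side"]
        elif eff == "Individual x Side" and "Error" in ms:
            denom, ddf = ms["Error"], df_by_effect["Error"]
        else:
            denom = None
        if denom:
            f = ms[eff] / denom
            p = float(stats.f.sf(f, df_by_effect[eff], ddf))
        rows.append((eff, ss_by_effect[eff], ms[eff], df_by_effect[eff], f, p))
    frame = pd.DataFrame(rows, columns=["Effect", "SS", "MS", "df", "F", "p"]).set_index("Effect")
    return AnovaTable(frame)


def procrustes_anova(
    dataset: LandmarkDataset,
    scheme: LandmarkScheme | None = None,
    fit: ProcrustesFit | None = None,
    df_override: dict[str, int] | None = None,
    n_perm: int = 0,
    seed: int = DEFAULT_SEED,
) -> AnovaTable:
    """Procrustes ANOVA of a replicated, object-symmetric landmark dataset.

    All replicate configurations and their relabeled mirror images are
    superimposed in one GPA; sums of squares are then pooled over the
    doubled sample:

    * Individual: symmetric deviations of specimen means from the grand
      mean symmetric shape;
    * Side: the directional-asymmetry vector (mean asymmetric component);
    * Individual x Side: fluctuating asymmetry (per-specimen deviation of
      the asymmetric component from DA);
    * Error: replicate deviations from the specimen mean, pooled over the
      symmetric and asymmetric subspaces.

    These strata are orthogonal, so they add up to the total Procrustes
    SS around the grand mean.  With a single replicate the Error row is
    absent and the interaction F cannot be formed.

    When ``n_perm > 0`` a sign-flip randomization of the per-specimen
    asymmetric components (sides exchangeable within individuals) yields
    permutation p-values for Side and the interaction, stored in
    ``AnovaTable.permutation_p``.
    """
    scheme = scheme or dataset.scheme
    n, r = dataset.n_specimens, dataset.n_replicates
    if n < 2:
        raise AnovaError("at least two specimens required")
    if fit is None:
        configs = dataset.coords.reshape(n * r, dataset.k, 3)
        fit = gpa(configs, scheme=scheme, include_mirrors=True)
    if not fit.include_mirrors:
        raise AnovaError("procrustes_anova requires an object-symmetry fit (include_mirrors)")
    comp = decompose_symmetry(fit, scheme)
    sym = comp.symmetric.reshape(n, r, dataset.k, 3)
    asym = comp.asymmetric.reshape(n, r, dataset.k, 3)

    sym_ind = sym.mean(axis=1)            # per-specimen symmetric mean
    asym_ind = asym.mean(axis=1)          # per-specimen asymmetric mean
    grand_sym = sym_ind.mean(axis=0)
    da = asym_ind.mean(axis=0)

    # factor 2: originals and mirrored copies both contribute to the SS
    ss = {
        "Individual": 2.0 * r * float(np.sum((sym_ind - grand_sym) ** 2)),
        "Side": 2.0 * n * r * float(np.sum(da**2)),
        "Individual x Side": 2.0 * r * float(np.sum((asym_ind - da) ** 2)),
    }
    if r >= 2:
        ss["Error"] = 2.0 * float(np.sum((sym - sym_ind[:, None]) ** 2)) + 2.0 * float(
            np.sum((asym - asym_ind[:, None]) ** 2)
        )

    p_pairs = len(scheme.bilateral_pairs())
    q_mid = len(scheme.midline_indices())
    d_sym, d_asym = symmetry_dimensions(p_pairs, q_mid)
    df = {
        "Individual": (n - 1) * d_sym,
        "Side": d_asym,
        "Individual x Side": (n - 1) * d_asym,
    }
    if r >= 2:
        df["Error"] = n * (r - 1) * (d_sym + d_asym)
    if df_override:
        df.update(df_override)
    table = anova_table_from_ss(ss, df)

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        ms_int_obs = ss["Individual x Side"] / df["Individual x Side"]
        f_side_obs = (ss["Side"] / df["Side"]) / ms_int_obs
        hits_side = 0
        hits_int = 0 if r >= 2 else None
        ms_err = (ss["Error"] / df["Error"]) if r >= 2 else None
        for _ in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)[:, None, None]
            flipped = asym_ind * signs
            da_p = flipped.mean(axis=0)
            ss_side = 2.0 * n * r * float(np.sum(da_p**2))
            ss_int = 2.0 * r * float(np.sum((flipped - da_p) ** 2))
            ms_int = ss_int / df["Individual x Side"]
            if (ss_side / df["Side"]) / ms_int >= f_side_obs:
                hits_side += 1
            if ms_err is not None:
                if ms_int / ms_err >= ms_int_obs / ms_err:
                    hits_int += 1
        table.permutation_p["Side"] = (1 + hits_side) / (n_perm + 1)
        if hits_int is not None:
            table.permutation_p["Individual x Side"] = (1 + hits_int) / (n_perm + 1)
    return table
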