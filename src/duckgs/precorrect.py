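"""Fixed-effect pre-correction of phenotypes.

Environmental fixed effects are removed from raw phenotypes by ordinary
least squares before the animal model is fitted, so the mixed model only
carries an intercept and the additive genetic effect.  Growth traits
measured at finishing (slaughter body weight, breast depth) additionally
carry the feeding-pen factor; breast depth is corrected for body weight
as a covariate.  The adjusted phenotype y* is the OLS residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class FixedEffectsSpec:
    """Fixed-effect model for one trait: treatment-coded categorical
    factors plus optional numeric covariates, with an intercept."""

    trait: str
    factors: tuple = ()
    covariates: tuple = ()

    def __post_init__(self):
        if self.trait in self.covariates:
            raise ValueError(f"{self.trait} cannot be its own covariate")

    def formula(self) -> str:
        terms = [f"C({f})" for f in self.factors]
        terms += [f"Q('{c}')" for c in self.covariates]
        rhs = " + ".join(terms) if terms else "1"
        return f"Q('{self.trait}') ~ {rhs}"


def default_trait_models(traits=None) -> dict:
    """Default per-trait fixed-effect models.

    Early-life and score traits (JW, PRF, GAIT, FPD) and ADG carry
    sexhatch and dam-age class; finishing traits (BW, BD) additionally
    carry feeding pen, and BD is corrected for BW as a covariate.
    """
    base = {
        "JW": FixedEffectsSpec("JW", ("sexhatch", "damage")),
        "PRF": FixedEffectsSpec("PRF", ("sexhatch", "damage")),
        "GAIT": FixedEffectsSpec("GAIT", ("sexhatch", "damage")),
        "FPD": FixedEffectsSpec("FPD", ("sexhatch", "damage")),
        "ADG": FixedEffectsSpec("ADG", ("sexhatch", "damage")),
        "BW": FixedEffectsSpec("BW", ("sexhatch", "damage", "pen")),
        "BD": FixedEffectsSpec("BD", ("sexhatch", "damage", "pen"), ("BW",)),
    }
    if traits is None:
        return base
    return {t: base.get(t, FixedEffectsSpec(t, ("sexhatch", "damage")))
            for t in traits}


@dataclass
class AdjustedPhenotypes:
    """Residual phenotypes y* for one trait."""

    trait: str
    y_star: pd.Series          # indexed by individual id
    spec: FixedEffectsSpec
    coefficients: pd.Series = field(repr=False, default=None)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.y_star.index, "trait": self.trait,
                             "y_star": self.y_star.to_numpy()})


def fit_fixed_effects(phenotypes: pd.DataFrame,
                      spec: FixedEffectsSpec) -> AdjustedPhenotypes:
    """OLS fit of the fixed-effect model; y* = observed - fitted.

    Rows with a missing response or covariate are dropped.  Aliased
    (rank-deficient) design columns are resolved by the pseudo-inverse,
    which leaves the residuals unchanged.  Raises if a factor column is
    absent or entirely missing.
    """
    cols = [spec.trait, *spec.factors, *spec.covariates]
    for c in cols:
        if c not in phenotypes.columns:
            raise ValueError(f"column {c!r} missing from phenotype table")
        if phenotypes[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
    data = phenotypes[["id", *cols]].dropna(subset=cols)
    if data.empty:
        raise ValueError(f"no complete records for trait {spec.trait}")
    res = smf.ols(spec.formula(), data=data).fit()
    y_star = pd.Series(res.resid.to_numpy(), index=data["id"].to_numpy(),
                       name=spec.trait)
    return AdjustedPhenotypes(trait=spec.trait, y_star=y_star, spec=spec,
                              coefficients=res.params)


def precorrect_all(phenotypes: pd.DataFrame, traits,
                   models: dict | None = None) -> dict:
    """Pre-correct several traits; returns {trait: AdjustedPhenotypes}."""
    models = models or default_trait_models(traits)
    return {t: fit_fixed_effects(phenotypes, models[t]) for t in traits}
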