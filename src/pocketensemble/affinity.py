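"""Experimental IC50 -> Ki -> binding free energy conversion and comparison.

Blebbistatin-like compounds act as mixed inhibitors of actin-activated
ATPase: they bind a tight site on the substrate-engaged (ADP*Pi) branch with
inhibition constant Ki and a weak site on the other branch with alpha * Ki.
Under the standard mixed-inhibition rate law the half-inhibitory
concentration satisfies

    IC50 = (S + Km) / (Km / (alpha * Ki) + S / Ki)

with S the substrate (actin) concentration and Km its Michaelis constant.
For the characterized skeletal-myosin case (S = 43 uM, Km = 24 uM,
alpha = 10) this gives IC50 / Ki ~ 1.5, i.e. IC50 is essentially Ki — the
``paper_assumption`` mode applies that identity directly.  Free energies use
dG = RT ln(Ki in molar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pocketensemble.constants import DEFAULT_TEMPERATURE_K, R_KCAL_PER_MOL_K

__all__ = [
    "InhibitionScheme",
    "ExperimentalAffinity",
    "ComparisonResult",
    "ic50_to_ki_mixed",
    "affinity_from_ic50",
    "compare_predictions",
]


@dataclass
class InhibitionScheme:
    """Mixed-inhibition parameters: substrate conc. S, Km (uM), affinity ratio alpha."""

    substrate_uM: float = 43.0
    km_uM: float = 24.0
    alpha: float = 10.0

    def __post_init__(self) -> None:
        if min(self.substrate_uM, self.km_uM, self.alpha) <= 0:
            raise ValueError("scheme parameters must be positive")


@dataclass
class ExperimentalAffinity:
    """One isoform's experimental inhibition datum converted to a free energy."""

    isoform: str
    ic50_uM: float | None
    ki_uM: float
    dG_kcal_mol: float
    se_kcal_mol: float | None = None


@dataclass
class ComparisonResult:
    """Agreement between predicted and experimental binding free energies."""

    r_squared: float  # squared Pearson correlation
    rmse: float  # kcal/mol
    r_squared_identity: float  # 1 - SS_res/SS_tot about the identity line
    pairs: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.r_squared > 1 + 1e-12 or self.rmse < 0:
            raise ValueError("invalid comparison statistics")


def ic50_to_ki_mixed(ic50_uM: float, scheme: InhibitionScheme | str = "paper_assumption"
                     ) -> float:
    """Solve the mixed-inhibition relation for Ki (uM).

    Ki = IC50 * (Km/alpha + S) / (S + Km).  At alpha = 1 (pure noncompetitive)
    Ki = IC50 exactly; as alpha -> inf the uncompetitive limit
    Ki -> IC50 / (1 + Km/S) is approached.  The string mode
    ``"paper_assumption"`` returns Ki = IC50.
    """
    if ic50_uM <= 0:
        raise ValueError("IC50 must be positive")
    if isinstance(scheme, str):
        if scheme != "paper_assumption":
            raise ValueError(f"unknown scheme {scheme!r}")
        return float(ic50_uM)
    s, km, a = scheme.substrate_uM, scheme.km_uM, scheme.alpha
    return float(ic50_uM * (km / a + s) / (s + km))


def affinity_from_ic50(
    ic50_uM: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    scheme: InhibitionScheme | str = "paper_assumption",
) -> float:
    """Binding free energy (kcal/mol) from an IC50: dG = RT ln(Ki [M])."""
    ki_uM = ic50_to_ki_mixed(ic50_uM, scheme)
    return float(R_KCAL_PER_MOL_K * temperature * np.log(ki_uM * 1e-6))


def compare_predictions(predicted, experimental) -> ComparisonResult:
    """R^2 (squared Pearson correlation) and RMSE between paired dG values.

    Also reports the coefficient of determination about the identity line
    (1 - SS_res/SS_tot), which penalizes systematic offsets; the Pearson
    form is the headline statistic.
    """
    p = np.asarray(predicted, float)
    e = np.asarray(experimental, float)
    if p.shape != e.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("need equal-length 1-D vectors with at least 2 entries")
    if np.std(p) == 0 or np.std(e) == 0:
        raise ValueError("zero variance in predictions or experiments")
    r = float(np.corrcoef(p, e)[0, 1])
    rmse = float(np.sqrt(np.mean((p - e) ** 2)))
    ss_res = float(np.sum((e - p) ** 2))
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    return ComparisonResult(
        r_squared=r**2,
        rmse=rmse,
        r_squared_identity=1.0 - ss_res / ss_tot,
        pairs=list(zip(p.tolist(), e.tolist())),
    )
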