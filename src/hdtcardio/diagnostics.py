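"""Residual diagnostics for the mixed models.

Normality and homoscedasticity of the mixed models are judged from residual
plots rather than formal tests; this module emits the figures and leaves the
judgement to the analyst.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy import stats

from .mixedlm import MixedFit


def residuals_vs_fitted(fit: MixedFit, title: str = ""):
    """Residuals-against-fitted scatter plus a normal Q-Q panel."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    resid = fit.resid
    ax1.scatter(fit.fitted, resid, s=12, alpha=0.7)
    ax1.axhline(0.0, color="grey", lw=0.8)
    ax1.set_xlabel("fitted value")
    ax1.set_ylabel("marginal residual")
    ax1.set_title(title or "residuals vs fitted")
    stats.probplot(resid, dist="norm", plot=ax2)
    ax2.set_title("normal Q-Q")
    fig.tight_layout()
    return fig
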