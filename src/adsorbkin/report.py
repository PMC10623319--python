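"""Goodness-of-fit reporting for population fits.

Produces the standard pharmacometric diagnostics stratified by circuit
port (pre- vs post-adsorber): observed vs population/individual
predictions, residuals over time, and a text/JSON summary with OFV, AIC,
the RSE table, eta shrinkage and the residual-error CVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import PKDataset, Port
from .estimate import FitResult

__all__ = ["gof_report"]

_PRE_PORTS = (Port.systemic.value, Port.inlet.value)


def _stratum(port: str) -> str:
    return "pre_adsorber" if port in _PRE_PORTS else "post_adsorber"


def gof_report(
    fit: FitResult,
    dataset: PKDataset,
    out_dir: str | Path | None = None,
) -> dict:
    """Assemble the goodness-of-fit bundle for a converged fit.

    Returns a dict with the diagnostic table (per observation: DV, PRED,
    IPRED, residuals, stratum) and a summary block. If ``out_dir`` is
    given, writes ``gof.csv``, ``summary.json`` and static plots there.
    """
    if not fit.converged:
        raise ValueError("goodness-of-fit report requires a converged fit")
    tab = fit.predictions.copy()
    tab["RES"] = tab["DV"] - tab["PRED"]
    tab["IRES"] = tab["DV"] - tab["IPRED"]
    tab["stratum"] = tab["PORT"].map(_stratum)

    strata = sorted(tab["stratum"].unique())
    residual_cv = {
        "pre_adsorber": fit.estimates.get("sigma_prop_pre"),
        "post_adsorber": fit.estimates.get("sigma_prop_post"),
    }
    summary = {
        "ofv": fit.ofv,
        "aic": fit.aic,
        "n_observations": int(len(tab)),
        "strata": strata,
        "estimates": fit.estimates,
        "rse_percent": fit.rse_percent,
        "shrinkage_percent": fit.shrinkage_percent,
        "residual_cv_by_stratum": residual_cv,
        "sigma_add": fit.estimates.get("sigma_add"),
        "max_abs_individual_residual": float(np.max(np.abs(tab["IRES"]))),
    }
    bundle = {"table": tab, "summary": summary}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tab.to_csv(out / "gof.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        _write_plots(tab, out)
    return bundle


def _write_plots(tab: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = sorted(tab["stratum"].unique())
    fig, axes = plt.subplots(2, len(strata), figsize=(5 * len(strata), 8), squeeze=False)
    for j, s in enumerate(strata):
        sub = tab[tab["stratum"] == s]
        ax = axes[0][j]
        ax.scatter(sub["PRED"], sub["DV"], s=12, alpha=0.6, label="population")
        ax.scatter(sub["IPRED"], sub["DV"], s=12, alpha=0.6, label="individual")
        lim = max(sub["DV"].max(), sub["PRED"].max(), 1e-9)
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("predicted (mg/L)")
        ax.set_ylabel("observed (mg/L)")
        ax.set_title(s.replace("_", " "))
        ax.legend(fontsize=8)
        ax = axes[1][j]
        ax.scatter(sub["TIME"], sub["IRES"], s=12, alpha=0.6)
        ax.axhline(0.0, color="k", lw=1, ls="--")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("individual residual (mg/L)")
    fig.tight_layout()
    fig.savefig(out / "gof.png", dpi=120)
    plt.close(fig)
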