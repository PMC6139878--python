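"""Self-contained HTML reports for ensemble fits.

The report shows the mean-MSE-vs-γ curve with the NEP optimum, overlays of
data and fitted model for individual profiles, a diameter histogram/box
summary, and a full echo of the configuration and seed that produced the
run.  Regenerating a report from the same results is byte-identical except
for the timestamp line.
"""

from __future__ import annotations

import base64
import datetime
import io
import json
from pathlib import Path

import numpy as np
from jinja2 import Template

from .fitting import ConvolvedProfileFitter, EnsembleFitResult
from .profiles import ProfileEnsemble

__all__ = ["generate_report"]

MAX_OVERLAY_PANELS = 16

_TEMPLATE = Template("""<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>NEP fit report</title>
<style>
body { font-family: sans-serif; margin: 2em; max-width: 60em; }
table { border-collapse: collapse; }
td, th { border: 1px solid #999; padding: 0.3em 0.8em; text-align: left; }
img { max-width: 100%; }
pre { background: #f4f4f4; padding: 1em; overflow-x: auto; }
</style></head>
<body>
<h1>Nested-loop ensemble PSF fit report</h1>
<p class="timestamp">Generated: {{ timestamp }}</p>
<h2>Summary</h2>
<table>
<tr><th>Ensemble PSF FWHM (&gamma;*)</th><td>{{ "%.1f"|format(psf_fwhm) }} nm</td></tr>
<tr><th>Tubule diameter (mean &plusmn; SD)</th>
    <td>{{ "%.1f"|format(diameter_mean) }} &plusmn; {{ "%.1f"|format(diameter_sd) }} nm</td></tr>
<tr><th>Geometry</th><td>{{ geometry_kind }}</td></tr>
<tr><th>Profiles (fitted / excluded)</th><td>{{ n_profiles }} / {{ n_excluded }}</td></tr>
<tr><th>&gamma; search bounds</th><td>{{ gamma_bounds[0] }} &ndash; {{ gamma_bounds[1] }} nm</td></tr>
</table>
<h2>Mean MSE vs PSF FWHM</h2>
<img src="data:image/png;base64,{{ mse_png }}" alt="mean MSE curve"/>
<h2>Profile fits{% if truncated %} (first {{ max_panels }} shown){% endif %}</h2>
<img src="data:image/png;base64,{{ overlay_png }}" alt="profile overlays"/>
<h2>Diameter distribution</h2>
<img src="data:image/png;base64,{{ diam_png }}" alt="diameter distribution"/>
<h2>Configuration</h2>
<pre>{{ config_echo }}</pre>
</body>
</html>
""")


def _fig_to_b64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    import matplotlib.pyplot as plt
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def generate_report(
    results: EnsembleFitResult,
    ensemble: ProfileEnsemble,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write a self-contained HTML report of an ensemble fit."""
    if not results.per_profile:
        raise ValueError("cannot report an ensemble fit with no profile results")
    path = Path(path)
    # validate writability before doing any plotting work
    fh = open(path, "w")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    try:
        gammas = np.array([g for g, _ in results.mse_curve])
        mses = np.array([m for _, m in results.mse_curve])
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(gammas, mses, "o-", ms=3)
        ax.annotate(
            f"γ* = {results.psf_fwhm:.1f} nm",
            xy=(results.psf_fwhm, mses.min()),
            xytext=(results.psf_fwhm, mses.min() + 0.4 * np.ptp(mses)),
            arrowprops=dict(arrowstyle="->", color="tab:blue"),
            ha="center", color="tab:blue",
        )
        ax.set_xlabel("PSF FWHM γ (nm)")
        ax.set_ylabel("mean MSE (ADU²)")
        fig.tight_layout()
        mse_png = _fig_to_b64(fig)

        n_show = min(len(results.per_profile), MAX_OVERLAY_PANELS)
        ncols = 4
        nrows = int(np.ceil(n_show / ncols))
        fig, axes = plt.subplots(nrows, ncols,
                                 figsize=(3 * ncols, 2.2 * nrows),
                                 squeeze=False)
        model = ConvolvedProfileFitter(
            geometry=results.geometry_kind, psf_fwhm=results.psf_fwhm
        )
        for k in range(nrows * ncols):
            ax = axes[k // ncols][k % ncols]
            if k >= n_show:
                ax.axis("off")
                continue
            r = results.per_profile[k]
            p = ensemble.profiles[k]
            ax.plot(p.positions, p.intensities, "k.", ms=3)
            if np.isfinite(r.diameter):
                xs = np.linspace(p.positions[0], p.positions[-1], 200)
                ax.plot(xs, model._model(xs, r.diameter, r.phot.amplitude,
                                         r.phot.center, r.phot.background,
                                         r.psf_fwhm), "g-", lw=1.2)
            ax.set_title(f"d = {r.diameter:.1f} nm", fontsize=8)
            ax.tick_params(labelsize=7)
        fig.tight_layout()
        overlay_png = _fig_to_b64(fig)

        diams = results.diameters
        fig, (ax1, ax2) = plt.subplots(
            1, 2, figsize=(6, 3), gridspec_kw={"width_ratios": [3, 1]}
        )
        ax1.hist(diams, bins=max(5, diams.size // 5), color="seagreen")
        ax1.set_xlabel("fitted diameter (nm)")
        ax1.set_ylabel("profiles")
        ax2.boxplot(diams, widths=0.5)
        ax2.set_xticks([])
        ax2.set_ylabel("diameter (nm)")
        fig.tight_layout()
        diam_png = _fig_to_b64(fig)

        config_echo = json.dumps(
            {"config": config or ensemble.metadata, "seed": seed}, indent=2
        )
        html = _TEMPLATE.render(
            timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
            psf_fwhm=results.psf_fwhm,
            diameter_mean=results.diameter_mean,
            diameter_sd=results.diameter_sd,
            geometry_kind=results.geometry_kind,
            n_profiles=len(results.per_profile) - results.n_excluded,
            n_excluded=results.n_excluded,
            gamma_bounds=list(results.gamma_bounds),
            mse_png=mse_png,
            overlay_png=overlay_png,
            diam_png=diam_png,
            truncated=len(results.per_profile) > MAX_OVERLAY_PANELS,
            max_panels=MAX_OVERLAY_PANELS,
            config_echo=config_echo,
        )
        fh.write(html)
    finally:
        fh.close()
    return path
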