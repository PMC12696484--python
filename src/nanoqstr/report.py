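"""QMRF-style model report: the five OECD items in one markdown document.

(1) endpoint definition, (2) unambiguous algorithm, (3) applicability
domain, (4) goodness-of-fit / robustness / predictivity, (5) mechanistic
interpretation — plus a machine-readable key-value block mirroring the
numeric results.
"""

from __future__ import annotations

import json


def _fmt(x, nd=3):
    if x is None:
        return "not computed"
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def _metrics_table(metrics: dict) -> str:
    lines = ["| Statistical measure | Test set | Training set |",
             "| --- | --- | --- |"]
    keymap = [("R²", "r2"), ("Adjusted R²", "adjusted_r2"), ("Mean absolute error", "mae"),
              ("Mean squared error", "mse"), ("Root mean squared error", "rmse")]
    te, tr = metrics.get("test", {}), metrics.get("train", {})
    for label, key in keymap:
        lines.append(f"| {label} | {_fmt(te.get(key))} | {_fmt(tr.get(key))} |")
    return "\n".join(lines)


def generate_report(state) -> str:
    """Render the report for a (possibly partially) populated pipeline state."""
    cfg = state.config
    res = state.results or {}
    cv = res.get("cv", {})
    val = res.get("validation", {})
    gt = val.get("golbraikh_tropsha", {})
    apd = res.get("apd", {})
    expl = res.get("explanation", {})

    sections = []
    sections.append("# QSTR model report\n")
    sections.append(
        "## 1. Defined endpoint\n\n"
        "In vitro cell viability (fraction of untreated control) of "
        "immortalised cell lines after 24 h exposure to spherical iron "
        "carbide nanoparticles; treatments with viability below 70 % of "
        "control are regarded as cytotoxic.\n"
    )
    algo = cv.get("winner", "not computed")
    params = cv.get("best_params", {}).get(algo, {})
    sections.append(
        "## 2. Unambiguous algorithm\n\n"
        f"- approach: {cfg.approach} (feature set of {len(state.features or [])} "
        f"attributes: {', '.join(state.features or []) or 'not computed'})\n"
        f"- selected algorithm: {algo} with hyperparameters {json.dumps(params)}\n"
        f"- tuning: randomised search, {cfg.n_draws} draws per algorithm, "
        f"nested 5-fold cross-validation, seed {cfg.seed}\n"
        f"- cross-validated MAE per algorithm: "
        f"{json.dumps({k: round(v, 4) for k, v in cv.get('mae_cv', {}).items()})}\n"
    )
    apd_lines = ["## 3. Applicability domain\n"]
    if apd:
        for metric in ("euclidean", "gower"):
            a = apd.get(metric, {})
            apd_lines.append(
                f"- {metric}: threshold = ⟨d⟩ + Z·σ = {_fmt(a.get('mean_retained'), 4)} + "
                f"{_fmt(a.get('Z'), 2)}·{_fmt(a.get('sd_retained'), 4)} = "
                f"{_fmt(a.get('threshold'), 4)}; "
                f"test-set in-domain fraction {_fmt(a.get('test_in_domain_fraction'))}"
            )
    else:
        apd_lines.append("not computed")
    sections.append("\n".join(apd_lines) + "\n")

    fit_lines = ["## 4. Goodness-of-fit, robustness and predictivity\n"]
    if res.get("metrics"):
        fit_lines.append(_metrics_table(res["metrics"]) + "\n")
    if gt:
        fit_lines.append("Golbraikh–Tropsha acceptability:\n")
        fit_lines.append("| Criterion | Value | Pass |\n| --- | --- | --- |")
        flags = gt.get("flags", {})
        rows = [
            ("R² > 0.6", gt.get("r2"), flags.get("r2_gt_0.6")),
            ("Q²loo > 0.5", gt.get("q2_loo"), flags.get("q2_loo_gt_0.5")),
            ("(r² − r0²)/r² < 0.1", gt.get("ratio"), None),
            ("(r² − r0'²)/r² < 0.1", gt.get("ratio_prime"), flags.get("ratio_lt_0.1")),
            ("0.85 < k < 1.15", gt.get("k"), None),
            ("0.85 < k' < 1.15", gt.get("k_prime"), flags.get("slope_in_window")),
        ]
        for label, value, flag in rows:
            mark = "" if flag is None else (" yes" if flag else " no")
            fit_lines.append(f"| {label} | {_fmt(value)} |{mark} |")
        fit_lines.append(f"\nOverall: {'PASS' if gt.get('passed') else 'FAIL'}\n")
    if val.get("y_scramble"):
        fit_lines.append(
            f"Y-scrambling over {len(val['y_scramble']['rounds'])} rounds: "
            f"verdict {val['y_scramble']['verdict']}\n"
        )
    if val.get("bootstrap"):
        b = val["bootstrap"]
        fit_lines.append(
            f"Bootstrap ({b['B']} resamples, {int(b['level']*100)} % percentile "
            f"intervals, out-of-bag scoring): MAE {b['mae_ci']}, R² {b['r2_ci']}\n"
        )
    sections.append("\n".join(fit_lines))

    mech = ["## 5. Mechanistic interpretation\n"]
    if expl.get("global_ranking"):
        mech.append("Features by mean |SHAP| (descending):\n")
        for f, s in expl["global_ranking"]:
            mech.append(f"- {f}: {s:.4f}")
        mech.append(
            "\nNegative attributions push the predicted viability down "
            "(toward cytotoxicity); positive attributions push it up."
        )
    else:
        mech.append("not computed")
    sections.append("\n".join(mech) + "\n")

    machine = {
        "config": cfg.to_dict(),
        "cv": cv,
        "metrics": res.get("metrics"),
        "validation": {k: v for k, v in val.items() if k != "y_scramble"},
        "apd": apd,
    }
    sections.append("## Machine-readable summary\n\n```json\n"
                    + json.dumps(machine, indent=1, default=str) + "\n```\n")
    return "\n".join(sections)
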