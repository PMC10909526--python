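"""End-to-end study runner: synthesis -> coherence -> parametrization -> inference.

``run_study`` executes the full analysis from a single config (YAML file or
dict): generate a cohort, epoch and equalize, compute multitaper coherence,
parametrize each spectrum, build the tracking table, estimate the acoustic
rates, and run the inference battery (band-coherence ANOVA with post-hocs,
peak-parameter ANOVAs, repeated-measures correlations with dominance
analysis, the tracking x vocoding absolute-difference ANOVA, the rate
decoder, and behavior tests). Every table is written as TSV with a JSON
sidecar carrying the settings and seed; ``make_report`` assembles a markdown
report mirroring the result structure.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import (
    DecoderSettings,
    abs_diff_table,
    aperiodic_variance_explained,
    apply_decoder,
    train_rate_decoder,
    vocoding_slope,
)
from .cohspec import band_average, epoch_signal, equalize_epochsets, mtm_coherence
from .paramfit import channel_average, parametrize_spectrum, qc_drop
from .rates import center_frequency, modulation_spectrum, syllable_rate
from .stats import (
    dominance,
    pairwise_posthoc,
    rm_anova_1way,
    rm_anova_2way,
    rmcorr,
    wilcoxon_vs_constant,
)
from .synthgen import CohortSpec, ConditionSpec, gen_behavior, gen_burst_audio, gen_cohort

__all__ = ["ConfigError", "demo_config", "load_config", "run_study", "make_report"]


class ConfigError(ValueError):
    pass


def demo_config(seed: int = 0, n_subjects: int = 12) -> dict:
    """The bundled three-condition study: clear speech and two vocoding levels.

    Tracking CFs rise from near the syllable rate (4.2 Hz) toward the
    acoustic modulation rate (5.5 Hz) while the overall coupling gain —
    periodic, aperiodic and broadband alike — falls, emulating the loss of
    intelligibility. Syllable rate 4 Hz, modulation rate 5.5 Hz.
    """
    return {
        "seed": seed,
        "n_subjects": n_subjects,
        "n_epochs": 60,
        "epoch_len": 4.0,
        "n_channels": 4,
        "rate": 100.0,
        "syllable_rate": 4.0,
        "smoothing": 2.0,
        "conditions": [
            {"name": "original", "tracking_cf": 4.2, "coupling_snr": 0.20,
             "aperiodic_snr": 0.5, "broadband_snr": 0.06, "env_mod_rate": 5.5},
            {"name": "vocoded7", "tracking_cf": 4.8, "coupling_snr": 0.14,
             "aperiodic_snr": 0.35, "broadband_snr": 0.042, "env_mod_rate": 5.5},
            {"name": "vocoded3", "tracking_cf": 5.3, "coupling_snr": 0.10,
             "aperiodic_snr": 0.25, "broadband_snr": 0.03, "env_mod_rate": 5.5},
        ],
        "behavior": {"hit_prob": {"original": 0.95, "vocoded7": 0.85, "vocoded3": 0.70},
                     "n_trials": 24},
        "decoder": {"enabled": True, "n_members": 10, "repetitions": 5},
        "aperiodic_sim": {"enabled": True, "snr_grid": [0.05, 0.1, 0.2, 0.4, 0.8],
                          "n_reps": 10, "duration": 120.0},
    }


_CONDITION_FIELDS = {"name", "tracking_cf"}
_CONDITION_OPTIONAL = {
    "tracking_bw", "coupling_snr", "aperiodic_snr", "broadband_snr",
    "noise_exponent", "env_mod_rate", "env_mod_bw", "env_mod_depth",
    "env_exponent",
}


def load_config(source: "str | Path | dict") -> dict:
    """Load and validate a study config; raises ConfigError naming bad fields."""
    if isinstance(source, (str, Path)):
        cfg = yaml.safe_load(Path(source).read_text())
    else:
        cfg = dict(source)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "conditions" not in cfg or not isinstance(cfg["conditions"], list):
        raise ConfigError("missing required field: conditions (list of condition specs)")
    if len(cfg["conditions"]) < 2:
        raise ConfigError("conditions: need at least 2 entries")
    for i, cond in enumerate(cfg["conditions"]):
        if not isinstance(cond, dict):
            raise ConfigError(f"conditions[{i}] must be a mapping")
        missing = _CONDITION_FIELDS - set(cond)
        if missing:
            raise ConfigError(f"conditions[{i}] missing fields: {sorted(missing)}")
        unknown = set(cond) - _CONDITION_FIELDS - _CONDITION_OPTIONAL
        if unknown:
            raise ConfigError(f"conditions[{i}] unknown fields: {sorted(unknown)}")
    for field, typ in [("n_subjects", int), ("seed", int)]:
        if field in cfg and not isinstance(cfg[field], int):
            raise ConfigError(f"{field} must be an integer")
    cfg.setdefault("seed", 0)
    cfg.setdefault("n_subjects", 12)
    cfg.setdefault("n_epochs", 60)
    cfg.setdefault("epoch_len", 4.0)
    cfg.setdefault("n_channels", 4)
    cfg.setdefault("rate", 100.0)
    cfg.setdefault("syllable_rate", 4.0)
    cfg.setdefault("band", [2.0, 7.0])
    # scaled-study default: ±2 Hz multitaper smoothing matches the spectral
    # resolution to the sub-Hz condition spacing of the synthetic cohorts
    # (see docs/methods.md); pass 4.0 to mirror the full-scale setting
    cfg.setdefault("smoothing", 2.0)
    cfg.setdefault("behavior", {"hit_prob": None, "n_trials": 24})
    cfg.setdefault("decoder", {"enabled": True, "n_members": 10, "repetitions": 5})
    cfg.setdefault(
        "aperiodic_sim",
        {"enabled": True, "snr_grid": [0.05, 0.1, 0.2, 0.4, 0.8], "n_reps": 10,
         "duration": 120.0},
    )
    return cfg


def _cohort_spec(cfg: dict) -> CohortSpec:
    conds = [ConditionSpec(**c) for c in cfg["conditions"]]
    return CohortSpec(
        n_subjects=cfg["n_subjects"],
        conditions=conds,
        n_epochs=cfg["n_epochs"],
        epoch_len=cfg["epoch_len"],
        n_channels=cfg["n_channels"],
        rate=cfg["rate"],
        seed=cfg["seed"],
    )


def _write(df: pd.DataFrame, path: Path, sidecar: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    side = dict(sidecar)
    side["package_version"] = __version__
    path.with_suffix(".json").write_text(json.dumps(side, indent=2, sort_keys=True, default=str))


def _stat_rows(results) -> pd.DataFrame:
    if isinstance(results, dict):
        results = list(results.values())
    if not isinstance(results, list):
        results = [results]
    return pd.DataFrame([r.as_row() for r in results])


def run_study(config: "str | Path | dict", out_dir: "str | Path") -> Path:
    """Run the full study described by ``config``; returns the results directory."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    band = tuple(cfg["band"])
    log: list[dict] = []

    def _stage(name):
        log.append({"stage": name, "t": time.time()})

    def _fail(stage, exc, ident=""):
        raise RuntimeError(f"stage {stage!r} failed on {ident or 'input'}: {exc}") from exc

    # --- synthesis -----------------------------------------------------
    _stage("synthgen")
    spec = _cohort_spec(cfg)
    records = gen_cohort(spec)
    cond_names = [c.name for c in spec.conditions]

    # --- acoustic rates ------------------------------------------------
    _stage("rates")
    rate_rows = []
    per_segment_mod_cfs: dict[str, list[float]] = {c: [] for c in cond_names}
    for cond in cond_names:
        cfs = []
        n_seg_total = 0
        for rec in records:
            if rec.condition != cond:
                continue
            freqs, spec_m, n_seg = modulation_spectrum(
                rec.envelope.samples, rec.envelope.rate, seg_len=6.0
            )
            cfs.append(center_frequency(freqs, spec_m, (1.0, 10.0)))
            n_seg_total += n_seg
            # per-segment CFs feed the decoder training pool
            seg_n = int(round(6.0 * rec.envelope.rate))
            for s in range(rec.envelope.samples.size // seg_n):
                seg = rec.envelope.samples[s * seg_n : (s + 1) * seg_n]
                fs, sp, _ = modulation_spectrum(seg, rec.envelope.rate, seg_len=6.0)
                per_segment_mod_cfs[cond].append(center_frequency(fs, sp, (1.0, 10.0)))
        rate_rows.append({"condition": cond, "modulation_cf": float(np.mean(cfs)),
                          "n_segments": n_seg_total})
    burst = gen_burst_audio(8000.0, 120.0, cfg["syllable_rate"], seed=cfg["seed"])
    syll = syllable_rate(burst.samples, burst.rate)
    rates_df = pd.DataFrame(rate_rows)
    rates_df["syllable_rate"] = syll
    _write(rates_df, out / "rates.tsv", {"seed": cfg["seed"], "syllable_rate_nominal": cfg["syllable_rate"]})

    # --- coherence + parametrization ----------------------------------
    _stage("cohspec+paramfit")
    rows = []
    for sid in sorted({r.subject_id for r in records}):
        subj = {r.condition: r for r in records if r.subject_id == sid}
        epoched = {
            c: (subj[c].epochs, epoch_signal(subj[c].envelope.samples, spec.rate, spec.epoch_len))
            for c in cond_names
        }
        epoched = equalize_epochsets(epoched, seed=cfg["seed"])
        for c in cond_names:
            es, env_ep = epoched[c]
            try:
                cs = mtm_coherence(es, env_ep, smoothing=cfg["smoothing"])
                fits = parametrize_spectrum(cs)
                if len(fits) >= 3:
                    fits, _droplog = qc_drop(fits)
                avg = channel_average(fits, band)
            except Exception as e:  # noqa: BLE001
                _fail("cohspec+paramfit", e, f"{sid}/{c}")
            row = {"subject": sid, "condition": c,
                   "band_coh": float(np.mean(band_average(cs, band))), **avg,
                   "true_cf": subj[c].true_cf, "true_snr": subj[c].true_snr}
            rows.append(row)
    tracking = pd.DataFrame(rows)
    tracking = abs_diff_table(tracking, rates_df)
    _write(tracking, out / "tracking_table.tsv", {"seed": cfg["seed"], "band": list(band)})

    # --- inference battery ---------------------------------------------
    _stage("stats")
    wide = tracking.pivot(index="subject", columns="condition", values="band_coh")[cond_names]
    band_res = [rm_anova_1way(wide.to_numpy(), effect="band_coh")]
    band_res += pairwise_posthoc(wide.to_numpy(), cond_names, method="paired_t")
    _write(_stat_rows(band_res), out / "stats_band.tsv", {"effect": "band coherence"})

    peak_rows = []
    for par in ("cf", "height", "bandwidth", "offset", "exponent"):
        wide_p = tracking.pivot(index="subject", columns="condition", values=par)[cond_names]
        if wide_p.isna().any().any():
            continue
        peak_rows.append(rm_anova_1way(wide_p.to_numpy(), effect=par))
    _write(_stat_rows(peak_rows), out / "stats_peaks.tsv", {"effect": "peak/aperiodic parameters"})

    slopes = vocoding_slope(tracking, cond_names)
    slopes.rename_axis("subject").reset_index().to_csv(out / "slopes.tsv", sep="\t", index=False)

    # rmcorr matrix + dominance against task performance
    _stage("rmcorr+dominance")
    beh_cfg = cfg["behavior"]
    hit_prob = beh_cfg.get("hit_prob") or {c: p for c, p in
                                           zip(cond_names, np.linspace(0.95, 0.70, len(cond_names)))}
    behavior = gen_behavior(cfg["n_subjects"], hit_prob, beh_cfg.get("n_trials", 24),
                            seed=cfg["seed"] + 1)
    _write(behavior, out / "behavior.tsv", {"hit_prob": hit_prob})
    beh_wide = behavior.pivot(index="subject", columns="condition", values="hit_rate")[cond_names]
    beh_res = [rm_anova_1way(beh_wide.to_numpy(), effect="hit_rate")]
    beh_res += pairwise_posthoc(beh_wide.to_numpy(), cond_names, method="wilcoxon")
    beh_res.append(wilcoxon_vs_constant(beh_wide.to_numpy().ravel(), 0.5))
    _write(_stat_rows(beh_res), out / "stats_behavior.tsv", {"chance": 0.5})

    merged = tracking.merge(behavior[["subject", "condition", "hit_rate"]],
                            on=["subject", "condition"])
    params = ["offset", "exponent", "cf", "height", "bandwidth", "band_coh", "hit_rate"]
    corr = pd.DataFrame(np.eye(len(params)), index=params, columns=params)
    pmat = corr.copy() * 0.0
    for i, a in enumerate(params):
        for j, b in enumerate(params):
            if j <= i:
                continue
            sub = merged[[a, b, "subject"]].dropna()
            try:
                r, _, p = rmcorr(sub[a], sub[b], sub["subject"])
            except ValueError:
                r, p = np.nan, np.nan
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    corr.rename_axis("parameter").reset_index().to_csv(out / "rmcorr_matrix.tsv", sep="\t", index=False)
    var_exp = aperiodic_variance_explained(merged)
    _write(var_exp, out / "variance_explained.tsv", {"target": "band_coh"})
    dom_payload: dict = {"predictors": params[:5], "outcome": "hit_rate"}
    try:
        dom, full_r2 = dominance(corr.loc[params[:5] + ["hit_rate"], params[:5] + ["hit_rate"]],
                                 outcome="hit_rate")
        dom_payload.update({"dominance": dom, "full_r2": full_r2,
                            "sum_check": float(sum(dom.values()))})
    except ValueError as e:
        dom_payload["error"] = str(e)
    (out / "dominance.json").write_text(json.dumps(dom_payload, indent=2, sort_keys=True))

    # --- tracking x vocoding absolute differences -----------------------
    _stage("attribution")
    ad = tracking.dropna(subset=["cf"])
    wide_mod = ad.pivot(index="subject", columns="condition", values="abs_diff_mod")[cond_names]
    wide_syl = ad.pivot(index="subject", columns="condition", values="abs_diff_syll")[cond_names]
    complete = wide_mod.dropna().index.intersection(wide_syl.dropna().index)
    arr = np.stack([wide_mod.loc[complete].to_numpy(), wide_syl.loc[complete].to_numpy()], axis=1)
    absdiff_res = rm_anova_2way(arr, factor_names=("tracking", "vocoding"))
    _write(_stat_rows(absdiff_res), out / "stats_absdiff.tsv",
           {"factors": ["tracking (mod/syll)", "vocoding"], "n_subjects": len(complete)})

    # --- decoder --------------------------------------------------------
    dec_cfg = cfg["decoder"]
    if dec_cfg.get("enabled", True):
        _stage("decoder")
        mod_pool = np.concatenate([np.asarray(v) for v in per_segment_mod_cfs.values()])
        seg_n = int(round(6.0 * burst.rate))
        syll_pool = np.array([
            syllable_rate(burst.samples[s * seg_n : (s + 1) * seg_n], burst.rate)
            for s in range(burst.samples.size // seg_n)
        ])
        rng = np.random.default_rng(cfg["seed"] + 2)
        n_per = min(mod_pool.size, max(syll_pool.size, 20))
        if mod_pool.size > n_per:
            mod_pool = rng.choice(mod_pool, size=n_per, replace=False)
        if syll_pool.size < n_per:  # resample with jitter to balance classes
            syll_pool = rng.choice(syll_pool, size=n_per, replace=True) + \
                0.05 * rng.standard_normal(n_per)
        settings = DecoderSettings(
            n_members=dec_cfg.get("n_members", 10),
            repetitions=dec_cfg.get("repetitions", 5),
        )
        values = np.concatenate([mod_pool, syll_pool])
        labels = np.array(["modulation"] * mod_pool.size + ["syllable"] * syll_pool.size)
        decoder = train_rate_decoder(values, labels, settings, seed=cfg["seed"] + 3)
        probs = apply_decoder(decoder, ad["cf"].to_numpy())
        probs.insert(0, "subject", ad["subject"].to_numpy())
        probs.insert(1, "condition", ad["condition"].to_numpy())
        _write(probs, out / "decoder_probs.tsv", {"held_out_auc": decoder.test_auc})
        (out / "decoder.json").write_text(json.dumps(
            {"neighbor_counts": decoder.neighbor_counts,
             "confusion": decoder.confusion.tolist(),
             "held_out_auc": decoder.test_auc,
             "settings": vars(decoder.settings), "seed": decoder.seed},
            indent=2, sort_keys=True))

    # --- aperiodic simulation curves ------------------------------------
    ap_cfg = cfg["aperiodic_sim"]
    if ap_cfg.get("enabled", True):
        _stage("aperiodic_sim")
        from .aperiodic_sim import coherence_slope_curve

        curve = coherence_slope_curve(
            ap_cfg.get("snr_grid", [0.05, 0.1, 0.2, 0.4, 0.8]),
            n_reps=ap_cfg.get("n_reps", 10),
            duration=ap_cfg.get("duration", 120.0),
            seed=cfg["seed"] + 4,
            smoothing=cfg["smoothing"],
        )
        _write(curve, out / "aperiodic_curve.tsv", {"seed": cfg["seed"] + 4})

    (out / "run_log.json").write_text(json.dumps(
        {"stages": log, "config": {k: v for k, v in cfg.items()},
         "package_version": __version__}, indent=2, default=str))
    make_report(out)
    return out


def _section(lines: list[str], title: str, path: Path, render) -> None:
    lines.append(f"\n## {title}\n")
    if not path.exists():
        lines.append(f"*MISSING: expected output `{path.name}` not found.*\n")
        return
    try:
        lines.extend(render(path))
    except Exception as e:  # noqa: BLE001
        lines.append(f"*MISSING: could not render `{path.name}`: {e}*\n")


def _tsv_block(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return ["```", df.to_string(index=False, float_format=lambda v: f"{v:.4g}"), "```", ""]


def make_report(results_dir: "str | Path") -> Path:
    """Assemble a markdown report from a results directory.

    Sections: band coherence, peak parameters, correlations + dominance,
    tracking attribution (abs-diff ANOVA + decoder), aperiodic simulations.
    Missing outputs are flagged, not fatal.
    """
    d = Path(results_dir)
    lines = ["# Study report", ""]
    _section(lines, "Band-averaged coherence (2-7 Hz)", d / "stats_band.tsv", _tsv_block)
    _section(lines, "Periodic and aperiodic parameters", d / "stats_peaks.tsv", _tsv_block)

    def _dom_render(path: Path) -> list[str]:
        out = _tsv_block(d / "rmcorr_matrix.tsv") if (d / "rmcorr_matrix.tsv").exists() else []
        payload = json.loads(path.read_text())
        if "dominance" in payload:
            out.append("General dominance (incremental R^2) for task performance:")
            for k, v in payload["dominance"].items():
                out.append(f"- {k}: {v:.4f}")
            out.append(
                f"\nCheck: sum of dominance weights {payload['sum_check']:.6f} "
                f"= full-model R^2 {payload['full_r2']:.6f}"
            )
        else:
            out.append(f"*Dominance unavailable: {payload.get('error', 'unknown')}*")
        out.append("")
        return out

    _section(lines, "Repeated-measures correlations and dominance", d / "dominance.json", _dom_render)

    def _absdiff_render(path: Path) -> list[str]:
        out = _tsv_block(path)
        if (d / "decoder_probs.tsv").exists():
            probs = pd.read_csv(d / "decoder_probs.tsv", sep="\t")
            out.append("Mean decoder P(modulation) per condition:")
            for cond, grp in probs.groupby("condition"):
                out.append(f"- {cond}: {grp['p_modulation'].mean():.3f}")
            out.append("")
        else:
            out.append("*MISSING: decoder output not found.*\n")
        return out

    _section(lines, "Tracking attribution (|CF - rate| and decoder)",
             d / "stats_absdiff.tsv", _absdiff_render)
    _section(lines, "Aperiodic simulations", d / "aperiodic_curve.tsv", _tsv_block)

    report = d / "report.md"
    report.write_text("\n".join(lines))
    return report
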