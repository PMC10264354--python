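"""End-to-end pipeline driver: simulate → detect → score → ERP → cluster →
EGG → peripheral physiology → group statistics.

Each stage can be toggled from the :class:`~gutwave.io.PipelineConfig`; a
stage failure halts the run with a stage-tagged error.  All outputs embed
the configuration hash and seed, and a fixed seed reproduces the report
bundle byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, egg, erp, periphys, stats, vibration
from .cluster import cluster_test, default_adjacency
from .io import PipelineConfig, events_to_frame, read_session, write_session
from .montage import POSTERIOR_CHANNELS
from .synth import simulate_session

__all__ = ["run_pipeline", "PipelineError"]

STIM_BLOCKS = ("normal", "enhanced")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def _subject_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_pipeline(config: PipelineConfig) -> dict:
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"# gutwave config_hash={cfg.hash()} seed={cfg.seed}\n"
    log_lines: list[str] = [f"config_hash={cfg.hash()} seed={cfg.seed}"]

    rows: list[tuple] = []
    erp_maps: dict[str, list[np.ndarray]] = {b: [] for b in STIM_BLOCKS}
    erp_labels: list[str] = []
    erp_times: np.ndarray | None = None
    behav_rows: list[dict] = []
    grand_erps: dict[str, list[np.ndarray]] = {b: [] for b in STIM_BLOCKS}
    egg_spectra: list = []

    seeds = _subject_seeds(cfg.seed, cfg.n_subjects)
    for si in range(cfg.n_subjects):
        subj = f"S{si + 1:02d}"

        # ---- acquire a session ------------------------------------------
        try:
            if cfg.sessions_dir is not None:
                rec, gt_events, presses, _ = read_session(Path(cfg.sessions_dir) / subj)
            elif cfg.stages["simulate"]:
                scfg = cfg.session_config(seeds[si])
                rec, gt_events, presses, gt = simulate_session(scfg)
                if cfg.save_recordings:
                    write_session(out / "sessions" / subj, rec, gt_events, presses, gt)
            else:
                raise ValueError("no sessions_dir given and simulation disabled")
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("simulate", e) from e
        log_lines.append(f"{subj}: session with {len(gt_events)} events, "
                         f"{len(presses[0])} presses")

        # ---- vibration detection ----------------------------------------
        try:
            if cfg.stages["detect"] and "stetho" in rec:
                expected = sum(1 for e in gt_events)
                det = vibration.detect_vibrations(rec["stetho"], expected)
                det = vibration.assign_conditions(det, rec.blocks)
                events = [{"onset_s": e.onset, "offset_s": e.offset,
                           "block": e.condition, "condition": e.condition,
                           "kind": "vibration"} for e in det if e.condition in STIM_BLOCKS]
                log_lines.append(f"{subj}: detected {len(events)} vibrations")
            else:
                events = list(gt_events)
        except Exception as e:
            raise PipelineError("detect", e) from e

        by_block = {b: [ev for ev in events if ev["block"] == b] for b in STIM_BLOCKS}

        # ---- behavioral scoring -----------------------------------------
        scored = {}
        if cfg.stages["score"]:
            try:
                for b in STIM_BLOCKS:
                    if not by_block[b]:
                        continue
                    sb = behavior.score_block(by_block[b], presses,
                                              rec.block(b).span, grace=cfg.grace_s)
                    scored[b] = sb
                    rows += [(subj, b, "a_prime", sb.a_prime),
                             (subj, b, "a_prime_norm", sb.a_prime_norm),
                             (subj, b, "tp_rate", sb.tp),
                             (subj, b, "fp_rate", sb.fp)]
                    if sb.latency_mean is not None:
                        rows.append((subj, b, "latency_mean", sb.latency_mean))
                    if sb.latency_sd is not None:
                        rows.append((subj, b, "latency_sd", sb.latency_sd))
                    behav_rows.append({"subject": subj, "block": b,
                                       "n_correct": sb.n_correct,
                                       "above_chance": sb.above_chance,
                                       "tp": sb.tp, "fp": sb.fp,
                                       "a_prime": sb.a_prime,
                                       "a_prime_norm": sb.a_prime_norm})
            except Exception as e:
                raise PipelineError("score", e) from e

        # ---- ERP ---------------------------------------------------------
        if cfg.stages["erp"] and "eeg" in rec:
            try:
                clean = erp.preprocess(rec["eeg"])
                clean = erp.rereference_mastoids(clean)
                ep_events = []
                for b, sb in scored.items():
                    hit_onsets = {round(o, 4) for o, outc in zip(
                        sb.per_event[sb.per_event.kind == "vibration"].onset_s,
                        sb.per_event[sb.per_event.kind == "vibration"].outcome)
                        if outc == "hit"}
                    for ev in by_block[b]:
                        cls = "true_positive" if round(ev["onset_s"], 4) in hit_onsets else "miss"
                        ep_events.append({"onset_s": ev["onset_s"],
                                          "condition": b, "cls": cls})
                eps = erp.epoch(clean, ep_events, class_filter="true_positive")
                eps = erp.reject_artifacts(eps)
                log_lines.append(f"{subj}: epochs {eps.counts()}")
                if erp_times is None:
                    erp_times, erp_labels = eps.times, eps.labels
                for b in STIM_BLOCKS:
                    e_b = erp.average_erp(eps, condition=b)
                    m = erp.lpp_metrics(e_b)
                    rows += [(subj, b, "lpp_amplitude", m.amplitude),
                             (subj, b, "lpp_latency", m.latency)]
                    erp_maps[b].append(e_b.mean)
                    grand_erps[b].append(e_b.mean)
            except Exception as e:
                raise PipelineError("erp", e) from e

        # ---- EGG ----------------------------------------------------------
        if cfg.stages["egg"] and "egg" in rec:
            try:
                for b in rec.blocks:
                    spec = egg.egg_spectrum(rec["egg"], b.span)
                    ct = egg.gastric_phase(rec["egg"], spec.peak_freq, span=b.span)
                    ct = egg.flag_artifact_cycles(ct)
                    clean_spec = egg.recompute_power_clean(rec["egg"].crop(*b.span), ct)
                    rows += [(subj, b.label, "egg_peak_cpm", clean_spec.peak_freq),
                             (subj, b.label, "egg_total_power", clean_spec.band_power["total"]),
                             (subj, b.label, "egg_normo_power", clean_spec.band_power["normogastria"]),
                             (subj, b.label, "egg_brady_power", clean_spec.band_power["bradygastria"]),
                             (subj, b.label, "egg_tachy_power", clean_spec.band_power["tachygastria"])]
                    if b.label == "baseline":
                        egg_spectra.append(clean_spec)
            except Exception as e:
                raise PipelineError("egg", e) from e

        # ---- peripheral physiology ---------------------------------------
        if cfg.stages["periphys"] and "ecg" in rec:
            try:
                r = periphys.detect_r_peaks(rec["ecg"])
                series = periphys.clean_ibis(r)
                base_block = rec.block("baseline")
                pseudo = periphys.make_pseudo_events(
                    base_block.span, n=cfg.n_pseudo, skip_s=cfg.pseudo_skip_s)
                ev_per_block = dict(by_block)
                ev_per_block["baseline"] = pseudo
                for b in rec.blocks:
                    sub = series.crop(b.span)
                    rows.append((subj, b.label, "tonic_hr",
                                 periphys.tonic_hr(series, b.span)))
                    if len(sub.clean) >= 2:
                        rows.append((subj, b.label, "sdnn", periphys.sdnn(sub)))
                    try:
                        plf, phf = periphys.plf_phf(sub)
                        rows += [(subj, b.label, "plf", plf), (subj, b.label, "phf", phf)]
                    except ValueError:
                        pass
                    br = periphys.estimate_br(series, b.span)
                    if np.isfinite(br):
                        rows.append((subj, b.label, "br", br))
                    evs = ev_per_block.get(b.label, [])
                    if evs:
                        d = periphys.phasic_hr(series, evs)
                        if len(d):
                            rows.append((subj, b.label, "phasic_hr",
                                         float(d.delta_bpm.mean())))
                        if "scr" in rec:
                            s = periphys.phasic_scr(rec["scr"], evs)
                            if len(s):
                                rows.append((subj, b.label, "phasic_scr",
                                             float(s.max_scr_us.mean())))
            except Exception as e:
                raise PipelineError("periphys", e) from e

    # ---- cluster test across subjects ------------------------------------
    cluster_out = None
    if cfg.stages["cluster"] and all(len(erp_maps[b]) >= 2 for b in STIM_BLOCKS):
        try:
            adj = default_adjacency(tuple(erp_labels), cfg.adjacency_max_dist)
            res = cluster_test(np.stack(erp_maps["enhanced"]),
                               np.stack(erp_maps["normal"]), adj,
                               n_perm=cfg.n_perm, alpha=cfg.cluster_alpha,
                               cf_alpha=cfg.cf_alpha, seed=seeds[-1] ^ 0x5EED)
            cluster_out = {
                "n_permutations": res.n_permutations,
                "cluster_forming_t": res.cluster_threshold,
                "alpha": res.alpha,
                "clusters": [{
                    "polarity": int(c.polarity), "mass": c.mass, "p": c.p,
                    "n_points": int(len(c.channels)),
                    "channels": sorted({erp_labels[i] for i in c.channels}),
                    "time_range_s": [float(erp_times[c.time_bins.min()]),
                                     float(erp_times[c.time_bins.max()])],
                } for c in res.clusters],
            }
        except Exception as e:
            raise PipelineError("cluster", e) from e

    table = stats.make_measure_table(rows)

    # ---- group statistics --------------------------------------------------
    stats_out = {}
    if cfg.stages["stats"] and len(table):
        try:
            table = stats.flag_outliers(table)
            stats_out["contrasts"] = {}

            def _contrast(measure, a, b, family=1):
                try:
                    r = stats.paired_contrast(table, measure, a, b, family)
                except ValueError:
                    return
                stats_out["contrasts"][f"{measure}:{a}>{b}"] = {
                    "t": r.t, "df": r.df, "p_raw": r.p_raw,
                    "p_bonferroni": r.p_bonferroni, "cohen_d": r.cohen_d,
                    "n_pairs": r.n_pairs}

            for m in ("a_prime_norm", "latency_mean", "latency_sd",
                      "lpp_amplitude", "lpp_latency"):
                _contrast(m, "enhanced", "normal")
            for m in ("tonic_hr", "sdnn", "phasic_hr", "phasic_scr",
                      "egg_total_power", "br", "plf", "phf"):
                for a, b in (("normal", "baseline"), ("enhanced", "baseline"),
                             ("enhanced", "normal")):
                    _contrast(m, a, b, family=3)

            # LPP-behavior association controlling for condition
            sub = table[table.block.isin(STIM_BLOCKS) & ~table.outlier]
            wide = sub.pivot_table(index=["subject", "block"], columns="measure",
                                   values="value")
            if {"lpp_amplitude", "a_prime_norm"} <= set(wide.columns):
                w = wide.dropna(subset=["lpp_amplitude", "a_prime_norm"])
                if len(w) >= 4:
                    rho, p = stats.partial_spearman(
                        w["lpp_amplitude"], w["a_prime_norm"],
                        w.index.get_level_values("block"))
                    stats_out["lpp_vs_accuracy_partial_spearman"] = {"rho": rho, "p": p}
        except Exception as e:
            raise PipelineError("stats", e) from e

    # ---- report bundle -----------------------------------------------------
    def _write_csv(df: pd.DataFrame, name: str):
        path = out / name
        with open(path, "w") as f:
            f.write(stamp)
            df.to_csv(f, index=False)
        return path

    _write_csv(table, "measures.csv")
    if behav_rows:
        _write_csv(pd.DataFrame(behav_rows), "behavior.csv")
    meta = {"config_hash": cfg.hash(), "seed": cfg.seed}
    (out / "config.json").write_text(json.dumps({**meta, "config": cfg.to_dict()},
                                                sort_keys=True, indent=1, default=str))
    if cluster_out is not None:
        (out / "clusters.json").write_text(json.dumps({**meta, **cluster_out},
                                                      sort_keys=True, indent=1))
    if stats_out:
        (out / "stats.json").write_text(json.dumps({**meta, **stats_out},
                                                   sort_keys=True, indent=1))
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")

    if cfg.figures:
        _figures(out, grand_erps, erp_times, erp_labels, egg_spectra)

    return {"table": table, "clusters": cluster_out, "stats": stats_out,
            "out_dir": out, "behavior": pd.DataFrame(behav_rows)}


def _figures(out: Path, grand_erps, times, labels, egg_spectra) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if times is not None and all(grand_erps.get(b) for b in STIM_BLOCKS):
        idx = [labels.index(c) for c in POSTERIOR_CHANNELS if c in labels]
        fig, ax = plt.subplots(figsize=(7, 4))
        for b, color in zip(STIM_BLOCKS, ("tab:blue", "tab:green")):
            g = np.mean([m[idx].mean(axis=0) for m in grand_erps[b]], axis=0)
            ax.plot(times, g, color=color, label=b)
        ax.axvspan(0.4, 0.72, color="0.9")
        ax.set(xlabel="time from vibration onset (s)", ylabel="amplitude (µV)",
               title="Posterior-midline ERP")
        ax.legend()
        fig.savefig(out / "erp_posterior.png", dpi=120)
        plt.close(fig)
    if egg_spectra:
        fig, ax = plt.subplots(figsize=(6, 4))
        for s in egg_spectra:
            sel = s.freq_cpm <= 12
            ax.plot(s.freq_cpm[sel], s.power[sel], alpha=0.6)
        ax.set(xlabel="frequency (cpm)", ylabel="power (µV²)",
               title="EGG spectra (baseline, per subject)")
        fig.savefig(out / "egg_spectra.png", dpi=120)
        plt.close(fig)
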