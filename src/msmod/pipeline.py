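"""End-to-end orchestration: simulate -> preprocess -> segment ->
backfit -> moderate.

A run is driven by one :class:`~msmod.config.RunConfig` and a seed; all
stage outputs (behavior table, per-subject statistics, group templates,
moderation report) land in the output directory together with the
resolved configuration and a log of every parameter, so a run is
reproducible bit-for-bit. Stage outputs are cached under a hash of the
configuration slice that feeds them and reused when it matches.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import backfit as bf
from . import moderation as mod
from . import preprocessing as pre
from . import segmentation as seg
from . import synthetic as syn
from .config import RunConfig, save_config, to_dict

__all__ = ["run_pipeline", "templates_to_json", "templates_from_json"]

log = logging.getLogger("msmod")


def _hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def templates_to_json(ts: seg.TemplateSet, channel_labels: list[str]) -> dict:
    return {
        "k": ts.k,
        "names": ts.names or [f"state{i}" for i in range(ts.k)],
        "channel_labels": channel_labels,
        "maps": ts.maps.tolist(),
        "gev": ts.gev,
        "cv_value": ts.cv_value,
        "source": ts.source,
    }


def templates_from_json(blob: dict) -> seg.TemplateSet:
    return seg.TemplateSet(
        maps=np.asarray(blob["maps"], dtype=float),
        k=int(blob["k"]),
        gev=blob.get("gev"),
        cv_value=blob.get("cv_value"),
        source=blob.get("source", "group"),
        names=blob.get("names"),
    )


def _preprocess_one(rec: pre.Recording, pcfg) -> pre.EpochedEEG:
    rec = pre.bandpass_filter(rec, pcfg.l_freq, pcfg.h_freq, order=pcfg.filter_order)
    rec = pre.average_reference(rec)
    return pre.epoch_and_reject(rec, pcfg.epoch_ms, pcfg.reject_uv)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis on a simulated cohort.

    Returns a bundle with the behavior table, per-subject statistics,
    the canonical group templates, the 24-row moderation report and the
    per-parameter moderation results; everything is also written to
    ``cfg.output_dir``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")
    save_config(cfg, out / "config.yaml")
    run_hash = _hash(to_dict(cfg))
    log.info("run %s -> %s", run_hash, out)

    stats_path = out / f"stats_{run_hash}.csv"
    behavior_path = out / f"behavior_{run_hash}.csv"
    templates_path = out / f"templates_{run_hash}.json"

    stage = "simulate"
    try:
        behavior, recordings, truth = syn.simulate_cohort(
            cfg.simulation, cfg.cohort, with_eeg=True
        )
        behavior.to_csv(behavior_path, index=False, float_format="%.10g")

        if stats_path.exists() and templates_path.exists():
            log.info("reusing cached statistics %s", stats_path.name)
            stats_df = pd.read_csv(stats_path)
            group = templates_from_json(json.loads(templates_path.read_text()))
        else:
            stage = "preprocess"
            epoch_list = []
            for sid, rec in zip(behavior["subject_id"], recordings):
                try:
                    epoch_list.append(_preprocess_one(rec, cfg.preprocessing))
                except Exception as exc:
                    raise RuntimeError(f"stage {stage} failed for {sid}: {exc}") from exc

            stage = "segment"
            subject_sets = []
            cv_by_k: dict[int, list[float]] = {}
            ks = sorted(set(cfg.segmentation.k_range))
            if cfg.segmentation.k_fixed is not None:
                ks = sorted(set(ks) | {int(cfg.segmentation.k_fixed)})
            rng = np.random.default_rng(cfg.seed)
            for sid, ep in zip(behavior["subject_id"], epoch_list):
                try:
                    peaks = seg.extract_peak_maps(
                        ep, cfg.segmentation.max_peaks, seed=int(rng.integers(2**31 - 1))
                    )
                    sets = seg.aahc_cluster(peaks, ks)
                except Exception as exc:
                    raise RuntimeError(f"stage {stage} failed for {sid}: {exc}") from exc
                for k, ts in sets.items():
                    if ts.cv_value is not None:
                        cv_by_k.setdefault(k, []).append(ts.cv_value)
                subject_sets.append(sets)
            mean_cv = {k: float(np.mean(v)) for k, v in cv_by_k.items()}
            if cfg.segmentation.k_fixed is not None:
                k_opt = int(cfg.segmentation.k_fixed)
                log.info("fixed k = %d (mean CV per k: %s)", k_opt, mean_cv)
            else:
                k_opt = min(mean_cv, key=lambda k: (mean_cv[k], k))
                log.info("CV-selected k = %d (mean CV per k: %s)", k_opt, mean_cv)
            group = seg.group_cluster([s[k_opt] for s in subject_sets], k_opt)
            if k_opt == 4:
                group, _ = bf.order_templates_canonically(group)

            stage = "backfit"
            stats_list = []
            gevs = []
            for sid, ep in zip(behavior["subject_id"], epoch_list):
                try:
                    labels = bf.backfit_labels(ep, group)
                    stats_list.append(bf.temporal_statistics(labels))
                    maps = ep.concatenated().T
                    gevs.append(
                        seg.compute_gev(
                            maps, maps.std(axis=1), group, labels.labels.ravel()
                        )
                    )
                except Exception as exc:
                    raise RuntimeError(f"stage {stage} failed for {sid}: {exc}") from exc
            group.gev = float(np.mean(gevs))
            group.gev_per_subject = np.asarray(gevs)
            log.info("group GEV %.3f +/- %.3f", np.mean(gevs), np.std(gevs, ddof=1) if len(gevs) > 1 else 0.0)
            stats_df = bf.stats_table(stats_list, list(behavior["subject_id"]))
            stats_df.to_csv(stats_path, index=False, float_format="%.10g")
            templates_path.write_text(
                json.dumps(templates_to_json(group, recordings[0].channel_labels), indent=1)
            )

        stage = "moderate"
        kept, excluded = mod.exclude_outliers(behavior, cfg.moderation.outlier_sd)
        stats_kept = stats_df[stats_df["subject_id"].isin(kept["subject_id"])]
        report, results = mod.run_moderation_battery(
            stats_kept, kept, alpha=cfg.moderation.alpha,
            probe_sds=cfg.moderation.probe_sds,
        )
        report.to_csv(out / "moderation_report.csv", index=False, float_format="%.10g")
        followup = {
            name: {
                "slopes": [vars(s) for s in res.slopes],
                "johnson_neyman": vars(res.jn) if res.jn else None,
            }
            for name, res in results.items()
            if res.p_fdr is not None and res.p_fdr < cfg.moderation.alpha
        }
        (out / "moderation_followup.json").write_text(json.dumps(followup, indent=1, default=float))
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    return {
        "behavior": behavior,
        "excluded_subjects": excluded,
        "stats": stats_df,
        "templates": group,
        "report": report,
        "results": results,
        "truth": truth,
        "output_dir": out,
    }
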