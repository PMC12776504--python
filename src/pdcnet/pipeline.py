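"""End-to-end orchestration: simulate -> preprocess -> beamform -> connect
-> graph/laterality -> statistics -> classification.

The pipeline operates on simulated cohorts with known ground truth (the
study's raw recordings are not redistributable); every stage is the public
library function, so intermediate artifacts can also be produced and
consumed individually through the CLI.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import beamform, classify, connectivity, groupstats, network, preprocess
from .atlas import default_atlas
from .config import PipelineConfig
from .containers import Recording, SourceEpochs
from .io import digest, write_connectivity, write_epochs, write_recording
from .preprocess import BandDefinition
from .synth import LeadField, generate_cohort

COMPARISONS = ("hc_vs_pre", "hc_vs_post", "pre_vs_post")


def config_bands(config: PipelineConfig) -> tuple[BandDefinition, ...]:
    return tuple(BandDefinition(b["name"], b["low_hz"], b["high_hz"])
                 for b in config.bands)


def preprocess_sensor(recording: Recording,
                      config: PipelineConfig) -> Recording:
    """Broadband filter then common-average re-reference."""
    rec = preprocess.bandpass_filter(recording, config.filter_low,
                                     config.filter_high, config.filter_order)
    return preprocess.common_average_reference(rec)


def localize(recording: Recording, leadfield: LeadField,
             config: PipelineConfig,
             rereferenced: bool = True) -> SourceEpochs:
    """LCMV source reconstruction, parcel reduction, epoching and flipping.

    ``rereferenced=True`` (the default pipeline) applies the same common-
    average projection to the leadfield that preprocessing applied to the
    data, keeping the forward model consistent with the recording reference.
    """
    lf_gain = leadfield.gain
    if rereferenced:
        lf_gain = lf_gain - lf_gain.mean(axis=0, keepdims=True)
        leadfield = LeadField(lf_gain, list(leadfield.sensor_labels),
                              list(leadfield.source_labels))
    cov = beamform.sensor_covariance(recording)
    filters = beamform.lcmv_filters(leadfield, cov,
                                    config.beamformer_regularization)
    sources = beamform.extract_virtual_channels(filters, recording)
    reduced = np.vstack([
        beamform.svd_reduce(row[None, :])[0] for row in sources.data
    ])
    sources.data = reduced
    epochs = preprocess.segment_epochs(
        sources, config.epoch_seconds, config.epoch_count,
        config.epoch_selection, seed=config.seed,
    )
    return preprocess.flip_hemispheres(epochs)


def subject_connectivity(epochs: SourceEpochs, config: PipelineConfig):
    candidates = tuple(range(2, config.mvar_max_order + 1))
    return connectivity.subject_connectivity(
        epochs, config_bands(config), order=config.mvar_order,
        order_candidates=candidates, squared=config.pdc_squared,
    )


def classifier_config(config: PipelineConfig,
                      subject_wise: bool = True) -> classify.ClassifierConfig:
    return classify.ClassifierConfig(
        c_grid=tuple(config.c_grid), scale_grid=tuple(config.scale_grid),
        k_grid=tuple(config.k_grid), inner_folds=config.inner_folds,
        relief_k_neighbors=config.relief_k_neighbors, seed=config.seed,
        subject_wise=subject_wise,
    )


def comparison_samples(conn_by_key: dict, band: str, comparison: str):
    """Assemble (matrices, labels, subject_ids) for one group comparison.

    Labels: 1 for the stroke/post class, 0 for the HC/pre class.
    """
    mats, labels, sids = [], [], []
    for (sid, session), by_band in conn_by_key.items():
        cm = by_band[band]
        if comparison == "hc_vs_pre":
            keep = (cm.group == "HC") or session == "pre"
            label = int(session == "pre")
        elif comparison == "hc_vs_post":
            keep = (cm.group == "HC") or session == "post"
            label = int(session == "post")
        elif comparison == "pre_vs_post":
            keep = session in ("pre", "post")
            label = int(session == "post")
        else:
            raise ValueError(f"unknown comparison {comparison!r}")
        if keep:
            mats.append(cm)
            labels.append(label)
            sids.append(sid)
    return mats, labels, sids


def run_pipeline(config: PipelineConfig, out_dir=None,
                 comparisons=COMPARISONS) -> dict:
    """Execute the full analysis on a simulated cohort.

    Returns a result dictionary (metrics tables, laterality, statistics,
    classification, manifest); writes CSV/JSON artifacts when ``out_dir``
    is given.
    """
    config.validate()
    t0 = time.time()
    atlas = default_atlas()
    bands = config_bands(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    recordings, truth, lf = generate_cohort(
        config.n_per_group, seed=config.seed, atlas=atlas,
        duration_s=config.duration_s, fs=config.fs,
        n_sensors=config.n_sensors, snr_db=config.snr_db,
    )

    conn, binnets = {}, {}
    metric_rows, li_rows = [], []
    stage_digests = {}
    for rec in recordings:
        key = (rec.subject_id, rec.session)
        try:
            clean = preprocess_sensor(rec, config)
            epochs = localize(clean, lf, config)
            by_band = subject_connectivity(epochs, config)
        except Exception as err:
            raise RuntimeError(
                f"stage failure for subject {rec.subject_id} "
                f"({rec.session or 'single'}): {err}"
            ) from err
        conn[key] = by_band
        if out is not None and config.save_recordings:
            write_recording(rec, out / "recordings" /
                            f"{rec.subject_id}_{rec.session or 'single'}.tsv")
        if out is not None and config.save_epochs:
            write_epochs(epochs, out / "epochs" /
                         f"{rec.subject_id}_{rec.session or 'single'}.npz")
        binnets[key] = {}
        for band in bands:
            cm = by_band[band.name]
            net = network.omst_binarize(cm, config.omst_max_rounds)
            binnets[key][band.name] = net
            s_out = network.node_strength(net, "out")
            s_in = network.node_strength(net, "in")
            deg = network.node_degree(net)
            eff = network.local_efficiency(net)
            for r, lab in enumerate(atlas.labels):
                metric_rows.append({
                    "subject_id": rec.subject_id, "group": rec.group,
                    "session": rec.session or "single", "band": band.name,
                    "region": lab, "strength_out": s_out[r],
                    "strength_in": s_in[r], "degree": int(deg[r]),
                    "local_efficiency": eff[r],
                })
            li = network.laterality_index(net, atlas, rec.subject_id,
                                          rec.session)
            for base, val in zip(li.base_regions, li.li):
                li_rows.append({
                    "subject_id": rec.subject_id, "group": rec.group,
                    "session": rec.session or "single", "band": band.name,
                    "region": base, "li": val,
                })
            if out is not None:
                write_connectivity(cm, out / "connectivity" / band.name /
                                   f"{rec.subject_id}_"
                                   f"{rec.session or 'single'}.csv")

    metrics = pd.DataFrame(metric_rows)
    laterality = pd.DataFrame(li_rows)
    stage_digests["connectivity"] = digest(np.concatenate([
        conn[k][b.name].weights.ravel() for k in sorted(conn) for b in bands
    ]))

    # group statistics on out-strength, per band and region
    stat_rows = []
    for band in bands:
        mb = metrics[metrics["band"] == band.name]
        hc = mb[mb["group"] == "HC"]
        pre = mb[mb["session"] == "pre"]
        post = mb[mb["session"] == "post"]
        for lab in atlas.labels:
            vals = {
                "hc": hc[hc["region"] == lab]["strength_out"].to_numpy(),
                "pre": pre[pre["region"] == lab]["strength_out"].to_numpy(),
                "post": post[post["region"] == lab]["strength_out"]
                .to_numpy(),
            }
            pairs = [("hc_vs_pre", "hc", "pre", False),
                     ("hc_vs_post", "hc", "post", False),
                     ("pre_vs_post", "pre", "post", True)]
            for name, a, b, paired in pairs:
                if name not in comparisons:
                    continue
                xa, xb = vals[a], vals[b]
                if len(xa) < 3 or len(xb) < 3:
                    continue
                if paired:
                    res = groupstats.compare_paired(
                        xa, xb, config.alpha_connectivity)
                else:
                    res = groupstats.compare_unpaired(
                        xa, xb, config.alpha_connectivity)
                stat_rows.append({
                    "comparison": name, "band": band.name, "region": lab,
                    "statistic": res.statistic, "p": res.p_value,
                    "d": res.effect_size_d, "test_used": res.test_used,
                    "significant": res.significant,
                })
    stats_table = pd.DataFrame(stat_rows)

    # laterality group tests
    li_tests = []
    for band in bands:
        lb = laterality[laterality["band"] == band.name]
        for cohort, sel in (("HC", lb["group"] == "HC"),
                            ("stroke_pre", lb["session"] == "pre"),
                            ("stroke_post", lb["session"] == "post")):
            sub = lb[sel]
            for base in atlas.base_names:
                x = sub[sub["region"] == base]["li"].dropna().to_numpy()
                if x.size < 3:
                    continue
                res = network.li_group_test(x, config.alpha_laterality)
                li_tests.append({"cohort": cohort, "band": band.name,
                                 "region": base, **res})
    li_tests = pd.DataFrame(li_tests)

    # clinical statistics on the packaged FMA table
    fma = groupstats.load_fma_table()
    fma_stats = groupstats.fma_summary(fma)
    anova = groupstats.mixed_anova(fma)
    correlations = {}
    stroke_ids = sorted({sid for (sid, s) in conn if s in ("pre", "post")})
    if len(stroke_ids) == len(fma) and "pre_vs_post" in comparisons:
        # positional pairing of simulated stroke subjects to clinical rows
        pairing = dict(zip(fma["subject_id"], stroke_ids))
        region = "dorsalA6-L"
        ridx = atlas.index(region)
        for band in bands:
            pre_map, post_map = {}, {}
            for clin_id, sim_id in pairing.items():
                wpre = conn[(sim_id, "pre")][band.name].weights
                wpost = conn[(sim_id, "post")][band.name].weights
                pre_map[clin_id] = float(wpre[:, ridx].sum())
                post_map[clin_id] = float(wpost[:, ridx].sum())
            r, p = groupstats.delta_correlation(fma, pre_map, post_map)
            correlations[band.name] = {"region": region, "r": r, "p": p}

    # band-wise classification
    clf_rows = []
    for band in bands:
        for comparison in comparisons:
            mats, labels, sids = comparison_samples(conn, band.name,
                                                    comparison)
            if len(set(labels)) < 2:
                continue
            ft = classify.vectorize(mats, labels, sids, band.name)
            try:
                m = classify.loocv_evaluate(ft, classifier_config(config))
            except ValueError:
                continue
            clf_rows.append({
                "band": band.name, "comparison": comparison,
                "accuracy": m.accuracy, "sensitivity": m.sensitivity,
                "specificity": m.specificity, "auc": m.auc,
            })
    classification = pd.DataFrame(clf_rows)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_recordings": len(recordings),
        "stage_digests": stage_digests,
        "elapsed_s": round(time.time() - t0, 2),
    }

    results = {
        "metrics": metrics, "laterality": laterality,
        "stats": stats_table, "li_tests": li_tests,
        "fma_summary": fma_stats, "mixed_anova": anova,
        "delta_correlations": correlations,
        "classification": classification, "manifest": manifest,
        "connectivity": conn, "binary_networks": binnets,
        "ground_truth": truth, "leadfield": lf,
    }

    if out is not None:
        metrics.to_csv(out / "node_metrics.csv", index=False)
        laterality.to_csv(out / "laterality.csv", index=False)
        stats_table.to_csv(out / "group_stats.csv", index=False)
        li_tests.to_csv(out / "laterality_tests.csv", index=False)
        classification.to_csv(out / "classification.csv", index=False)
        anova.to_csv(out / "fma_mixed_anova.csv", index=False)
        summary = {k: v for k, v in fma_stats.items() if k != "paired"}
        summary["paired_p"] = fma_stats["paired"].p_value
        summary["paired_d"] = fma_stats["paired"].effect_size_d
        (out / "fma_summary.json").write_text(json.dumps(summary, indent=1))
        (out / "delta_correlations.json").write_text(
            json.dumps(correlations, indent=1))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results
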