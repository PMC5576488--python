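"""End-to-end orchestration: behavior -> ripple detection -> unit
classification -> content statistics -> PFC modulation -> report.

The pipeline is a pure function of (session, config, seed); every number
in the report is the output of one of the stage operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import content as cont
from . import correlate as corr
from . import pfc as pfcmod
from . import place
from . import ripples as rip
from .config import DEFAULTS, load_config
from .model import Session
from .synth import GroundTruth

__all__ = [
    "ReportBundle",
    "run_pipeline",
    "verify_reference_anchors",
    "match_events",
    "place_label_accuracy",
    "pfc_group_accuracy",
]


@dataclass
class ReportBundle:
    """Structured pipeline outputs (one session)."""

    seed: int
    config: dict
    segmentation: beh.MotionSegmentation = None
    speed: np.ndarray = None
    events: list = field(default_factory=list)
    noise_model: rip.NoiseModel = None
    unit_table: pd.DataFrame = None
    content: cont.ContentCounts = None
    coactivity: pd.DataFrame = None
    latency: dict = field(default_factory=dict)
    event_summary: dict = field(default_factory=dict)
    pfc_table: pd.DataFrame = None
    group_summary: dict = field(default_factory=dict)
    joint_regression: dict = field(default_factory=dict)
    similarity: dict = field(default_factory=dict)
    coincidence: dict = field(default_factory=dict)

    def summary(self) -> dict:
        c = self.content
        out = {
            "n_events": len(self.events),
            "seed": self.seed,
        }
        if c is not None:
            out["content_counts"] = {
                "MAP-only": c.n_map_only, "IAP-only": c.n_iap_only,
                "joint": c.n_joint, "expected_joint": c.expected_joint_rounded,
                "chi2": c.chi2_stat, "p": c.p_value,
            }
        if self.group_summary:
            out["pfc_groups"] = self.group_summary
        return out


def run_pipeline(
    session: Session,
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_coactivity_permutations: int | None = None,
) -> ReportBundle:
    """Run every analysis stage on a session and assemble the report."""
    cfg = config or load_config(None)
    report = ReportBundle(seed=int(seed), config=cfg)

    # ---- behavior ----------------------------------------------------
    bcfg = cfg["behavior"]
    speed = session.position.speed_cm_s
    if speed is None:
        speed = beh.compute_speed(session.position, bcfg["speed_smoothing_sigma_s"])
    seg = beh.segment_motion(session.position, speed, bcfg["speed_threshold_cm_s"])
    report.segmentation, report.speed = seg, speed
    well_iv = beh.well_occupancy_intervals(session, seg)
    occ = beh.occupancy_map(session.position, bcfg["occupancy_bin_cm"])

    # ---- ripple detection --------------------------------------------
    dcfg = cfg["swr_detection"]
    filtered = rip.ripple_bandpass(session.lfp, band=tuple(dcfg["ripple_band"]))
    lfp_t = session.lfp.times()
    imm_mask = seg.state_at(lfp_t) == "immobility"
    env = rip.consensus_envelope(
        filtered, session.lfp.sample_rate_hz, imm_mask,
        dcfg["envelope_smoothing_sigma_s"], dcfg["min_channels"], session.lfp.t0_s,
    )
    noise = rip.estimate_noise_threshold(
        env.value, imm_mask, dcfg["noise_percentile"], dcfg["mode_bins"]
    )
    events = rip.detect_swrs(env, noise, seg, dcfg["min_event_ms"] / 1000.0)
    rip.swr_band_power(session.lfp, events, tuple(dcfg["ripple_band"]),
                       dcfg["spectrogram_window_s"], dcfg["spectrogram_step_s"])
    report.noise_model, report.events = noise, events

    # ---- CA1 unit classification -------------------------------------
    pcfg = cfg["place_coding"]
    duration = session.duration_s
    rows = []
    ca1 = session.units_in("CA1")
    spikes_by_unit = {u.unit_id: u.spike_times_s for u in session.units}
    well_ids = sorted(well_iv)
    for u in ca1:
        cell_class = place.classify_cell_class(
            u.spike_width_ms, u.mean_rate_hz(duration),
            pcfg["interneuron_max_width_ms"], pcfg["interneuron_min_rate_hz"],
        )
        rec = {"unit_id": u.unit_id, "cell_class": cell_class, "place_class": "excluded",
               "preferred_well": "", "specificity": np.nan,
               "median_speed": np.nan, "coverage": np.nan}
        if cell_class == "pyramidal":
            rates = place.immobility_well_rates(u, well_iv, events)
            rec["place_class"] = place.classify_place_class(
                rates, u.n_spikes, pcfg["min_spikes"], pcfg["iap_min_well_rate_hz"]
            )
            vec = np.array([rates[w] for w in well_ids])
            if np.any(np.nan_to_num(vec) > 0):
                rec["specificity"] = place.well_specificity(vec)
                rec["preferred_well"] = well_ids[int(np.nanargmax(vec))]
            rec["median_speed"] = place.median_speed_per_spike(u, session.position, speed)
            rmap = place.rate_map(u, occ, session.position,
                                  pcfg["ratemap_sigma_cm"], pcfg["ratemap_extent_cm"])
            rec["coverage"] = place.place_coverage(
                rmap, occ, pcfg["coverage_threshold_frac"], pcfg["coverage_min_occupancy_s"]
            )
        rows.append(rec)
    unit_table = pd.DataFrame(rows)
    report.unit_table = unit_table
    place_class = dict(zip(unit_table.unit_id, unit_table.place_class))

    # ---- ripple content ----------------------------------------------
    ccfg = cfg["swr_content"]
    cont.assign_content(events, place_class, spikes_by_unit)
    classified = [e for e in events if e.content_class != "neither"]
    if classified:
        report.content = cont.content_counts(events)
        report.latency = cont.in_swr_latency(events, place_class, spikes_by_unit)
        try:
            report.event_summary = cont.event_property_summary(events)
        except ValueError:
            report.event_summary = {}

    n_perm = n_coactivity_permutations or ccfg["n_permutations"]
    place_units = sorted(u for u, c in place_class.items() if c in ("IAP", "MAP"))
    part, part_ids = cont.participation_matrix(
        events, {u: spikes_by_unit[u] for u in place_units}
    ) if place_units and events else (np.zeros((0, 0), dtype=bool), [])
    co_rows = []
    for i, ua in enumerate(part_ids):
        for ub in part_ids[i + 1:]:
            j = part_ids.index(ub)
            eligible = cont.pair_eligibility(
                spikes_by_unit[ua], spikes_by_unit[ub],
                ccfg["eligibility_peak_lag_s"],
            )
            res = cont.coactivity_z(
                part[:, i], part[:, j], n_perm, cont.pair_seed(seed, ua, ub), (ua, ub)
            )
            co_rows.append({
                "unit_a": ua, "unit_b": ub,
                "pair_type": "-".join(sorted((place_class[ua], place_class[ub]))),
                "observed": res.observed_joint_fraction,
                "null_mean": res.null_mean, "null_sd": res.null_sd, "z": res.z,
                "eligible": eligible and not res.degenerate,
            })
    report.coactivity = pd.DataFrame(co_rows)

    # ---- PFC modulation ----------------------------------------------
    mcfg = cfg["pfc_modulation"]
    events_by_class = {
        c: [e for e in events if e.content_class == c]
        for c in ("MAP-only", "IAP-only", "joint")
    }
    move_iv = seg.intervals_of("movement")
    imm_iv = seg.intervals_of("immobility")
    from .model import spikes_in_intervals, total_interval_time

    pfc_rows = []
    for u in session.units_in("PFC"):
        t = u.spike_times_s
        r_move = spikes_in_intervals(t, move_iv).sum() / max(total_interval_time(move_iv), 1e-9)
        r_imm = spikes_in_intervals(t, imm_iv).sum() / max(total_interval_time(imm_iv), 1e-9)
        if max(r_move, r_imm) <= mcfg["min_rate_hz"]:
            continue
        rec = {"unit_id": u.unit_id}
        sig = {}
        for cls_name, key in (("IAP-only", "iap"), ("MAP-only", "map"), ("joint", "joint")):
            evs = events_by_class[cls_name]
            if len(evs) < mcfg["min_events"]:
                rec[f"i_{key}"] = np.nan
                rec[f"p_{key}"] = np.nan
                sig[key] = "n.s."
                continue
            res = pfcmod.modulation_with_significance(
                t, evs, u.unit_id, cls_name,
                n_permutations=mcfg["n_permutations"],
                seed=cont.pair_seed(seed, u.unit_id, cls_name),
                alpha=mcfg["alpha"], min_events=mcfg["min_events"],
            )
            rec[f"i_{key}"] = res.i_swr
            rec[f"p_{key}"] = res.p_value
            sig[key] = res.significance
        rec["sig_iap"], rec["sig_map"] = sig.get("iap", "n.s."), sig.get("map", "n.s.")
        rec["group"] = pfcmod.classify_group(rec["sig_iap"], rec["sig_map"])
        pfc_rows.append(rec)
    pfc_table = pd.DataFrame(pfc_rows)
    report.pfc_table = pfc_table

    if len(pfc_table):
        significant = pfc_table[pfc_table.group != "unclassified"]
        n_sig = len(significant)
        expected = pfcmod.expected_group_counts(n_sig, mcfg["combos_per_group"])
        groups = {}
        for g, combos in mcfg["combos_per_group"].items():
            obs = int((significant.group == g).sum())
            groups[g] = {
                "observed": obs, "expected": expected[g],
                "binomial_p": pfcmod.group_binomial_test(obs, n_sig, combos) if n_sig else np.nan,
            }
        report.group_summary = {"n_significant": n_sig, "groups": groups}
        try:
            report.joint_regression = pfcmod.joint_modulation_regression(
                pfc_table.i_joint.to_numpy(), pfc_table.i_map.to_numpy(),
                pfc_table.i_iap.to_numpy(),
            )
        except ValueError:
            report.joint_regression = {}

    # ---- PFC/CA1 task-firing comparison ------------------------------
    tcfg = cfg["temporal_correlation"]
    entries = np.array([e.time_s for e in session.well_events if e.kind == "entry"])
    if entries.size and len(pfc_table):
        peth_kw = dict(window_s=tcfg["peth_window_s"], bin_s=tcfg["peth_bin_s"],
                       smoothing_sigma_s=tcfg["peth_smoothing_sigma_s"])
        iap_units = [u for u, c in place_class.items() if c == "IAP"]
        map_units = [u for u, c in place_class.items() if c == "MAP"]
        iap_peths = [corr.well_entry_peth(spikes_by_unit[u], entries, **peth_kw)
                     for u in iap_units]
        map_peths = [corr.well_entry_peth(spikes_by_unit[u], entries, **peth_kw)
                     for u in map_units]
        ev_iv = np.array([[e.start_s, e.end_s] for e in events]).reshape(-1, 2)
        sim: dict[str, list] = {}
        coin: dict[str, list] = {}
        for rec in pfc_rows:
            uid, grp = rec["unit_id"], rec["group"]
            p_peth = corr.well_entry_peth(spikes_by_unit[uid], entries, **peth_kw)
            sim.setdefault(grp, []).extend(
                corr.pattern_similarity_index(p_peth, iap_peths, map_peths)
            )
            coin.setdefault(grp, []).extend(
                corr.coincidence_index(
                    spikes_by_unit[uid],
                    [spikes_by_unit[u] for u in iap_units],
                    [spikes_by_unit[u] for u in map_units],
                    exclude_intervals=ev_iv,
                    bin_s=tcfg["coincidence_bin_s"],
                    window_s=tcfg["coincidence_window_s"],
                    min_coincidences=tcfg["min_coincidences"],
                )
            )
        report.similarity = {g: np.asarray(v) for g, v in sim.items()}
        report.coincidence = {g: np.asarray(v) for g, v in coin.items()}

    if out_dir is not None:
        _write_outputs(report, Path(out_dir))
    return report


def _write_outputs(report: ReportBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"event_id": i, "start_s": e.start_s, "end_s": e.end_s,
          "duration_s": e.duration_s, "peak_env": e.peak_env,
          "band_power_z": e.band_power_z, "class": e.content_class}
         for i, e in enumerate(report.events)]
    ).to_csv(out / "swr_events.csv", index=False)
    pd.DataFrame(
        [{"state": st, "start_s": s, "end_s": e}
         for st, s, e in report.segmentation.intervals]
    ).to_csv(out / "segments.csv", index=False)
    if report.unit_table is not None:
        report.unit_table.to_csv(out / "unit_classification.csv", index=False)
    if report.coactivity is not None:
        report.coactivity.to_csv(out / "coactivity.csv", index=False)
    if report.pfc_table is not None:
        report.pfc_table.to_csv(out / "pfc_modulation.csv", index=False)
    if report.latency:
        pd.DataFrame(
            [{"place_class": c, "latency_s": v} for c, arr in report.latency.items()
             for v in arr]
        ).to_csv(out / "latency.csv", index=False)
    summary = report.summary()
    if report.group_summary:
        (out / "group_summary.json").write_text(
            json.dumps(report.group_summary, indent=2, default=float))
    if report.content is not None:
        c = report.content
        (out / "content_counts.json").write_text(json.dumps({
            "n_map_only": c.n_map_only, "n_iap_only": c.n_iap_only,
            "n_joint": c.n_joint, "expected_joint": c.expected_joint,
            "chi2": c.chi2_stat, "p_value": c.p_value}, indent=2, default=float))
    (out / "report.json").write_text(json.dumps(summary, indent=2, default=float))


# ---------------------------------------------------------------------------
# printed-value anchors


def verify_reference_anchors() -> pd.DataFrame:
    """Recompute the arithmetic anchors that need no recorded data.

    Uses the printed event counts (12881 MAP-only, 5009 IAP-only, 1311
    joint) and the 70-unit, 8-combination group accounting; each row
    reports the computed value, the anchor, and whether they agree.
    """
    rows = []

    cc = cont.content_counts((12881, 5009, 1311))
    rows.append(("expected_joint_count", cc.expected_joint_rounded, 4671))
    rows.append(("expected_joint_pct", round(100 * cc.expected_joint / cc.n_total), 24))
    rows.append(("map_only_pct", round(100 * cc.n_map_only / cc.n_total), 67))
    rows.append(("iap_only_pct", round(100 * cc.n_iap_only / cc.n_total), 26))
    rows.append(("joint_pct", round(100 * cc.n_joint / cc.n_total), 7))
    rows.append(
        ("pure_event_pct", round(100 * (cc.n_map_only + cc.n_iap_only) / cc.n_total), 93)
    )
    rows.append(("chi2_p_below_1e4", cc.p_value < 1e-4, True))

    expected = pfcmod.expected_group_counts(70)
    rows.append(("expected_iap_plus", expected["IAP-SWR+"], 18))
    rows.append(("expected_inhibited", expected["IAP/MAP-SWR-"], 26))
    rows.append(("expected_both_plus", expected["IAP-and-MAP-SWR+"], 9))
    rows.append(
        ("both_plus_binomial_p_below_05",
         pfcmod.group_binomial_test(3, 70, 1) < 0.05, True)
    )

    rows.append(("specificity_single_well", place.well_specificity([5.0, 0, 0, 0]), 1.0))
    rows.append(("specificity_equal_wells", place.well_specificity([3.0, 3, 3, 3]), 0.0))

    df = pd.DataFrame(rows, columns=["anchor", "computed", "expected"])
    df["pass"] = [
        bool(np.isclose(float(c), float(e), atol=1e-9))
        if isinstance(c, (int, float, np.floating)) else c == e
        for c, e in zip(df.computed, df.expected)
    ]
    return df


# ---------------------------------------------------------------------------
# ground-truth evaluation


def match_events(detected: list, truth_events: list) -> dict:
    """Match detected ripples to ground-truth ones by interval overlap.

    Greedy one-to-one matching; returns recall, precision and the start/
    end boundary errors (seconds) of matched pairs.
    """
    det = sorted(detected, key=lambda e: e.start_s)
    tru = sorted(truth_events, key=lambda e: e.start_s)
    used = np.zeros(len(det), dtype=bool)
    starts = np.array([e.start_s for e in det])
    boundary_err: list[float] = []
    n_match = 0
    for tv in tru:
        lo = np.searchsorted(starts, tv.start_s - 1.0)
        best, best_ov = -1, 0.0
        for k in range(lo, len(det)):
            if det[k].start_s > tv.end_s:
                break
            if used[k]:
                continue
            ov = min(det[k].end_s, tv.end_s) - max(det[k].start_s, tv.start_s)
            if ov > best_ov:
                best, best_ov = k, ov
        if best >= 0 and best_ov > 0:
            used[best] = True
            n_match += 1
            boundary_err.append(abs(det[best].start_s - tv.start_s))
            boundary_err.append(abs(det[best].end_s - tv.end_s))
    recall = n_match / len(tru) if tru else float("nan")
    precision = n_match / len(det) if det else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_matched": n_match,
        "median_boundary_error_s": float(np.median(boundary_err)) if boundary_err else float("nan"),
    }


def place_label_accuracy(unit_table: pd.DataFrame, truth: GroundTruth) -> float:
    """Fraction of true MAP/IAP units assigned their true place class."""
    pred = dict(zip(unit_table.unit_id, unit_table.place_class))
    hits = total = 0
    for uid, lab in truth.unit_labels.items():
        if lab["type"] not in ("MAP", "IAP"):
            continue
        total += 1
        hits += pred.get(uid) == lab["type"]
    return hits / total if total else float("nan")


_GROUP_BY_PROFILE = {
    "IAP-locked": "IAP-SWR+",
    "MAP-locked": "MAP-SWR+",
    "inhibited": "IAP/MAP-SWR-",
    "flat": "unclassified",
}


def pfc_group_accuracy(pfc_table: pd.DataFrame, truth: GroundTruth) -> float:
    """Fraction of PFC units assigned the group implied by their true gains."""
    pred = dict(zip(pfc_table.unit_id, pfc_table.group))
    hits = total = 0
    for uid, lab in truth.unit_labels.items():
        if lab["type"] != "PFC":
            continue
        total += 1
        hits += pred.get(uid) == _GROUP_BY_PROFILE[lab["group"]]
    return hits / total if total else float("nan")
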