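"""Scan orchestration: QC -> PAR -> (eROHi | iHS/nSL | HRiD) -> networks.

All tabular outputs are TSV with 1-based closed coordinates and literal
``NA`` for missing values; BED companions are 0-based half-open.  A run log
records the configuration verbatim, a hash of it and the seed, so identical
inputs and configuration reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import erohi as _erohi
from . import genotype_io as gio
from . import haplo_stats as hs
from . import haplonet as hn
from . import hrid as _hrid

logger = logging.getLogger(__name__)

_TSV_HEADER = "# coordinates: 1-based closed; missing values: NA\n"


@dataclass
class RunConfig:
    out_prefix: str = "scan"
    seed: int = 0
    # QC
    snp_call_rate: float = 0.90
    hwe_p: float = 1e-7
    ind_call_rate: float = 0.95
    gentrain: float = 0.4
    gencall: float = 0.8
    # PAR
    par_window_snps: int = 50
    par_het_floor: float = 0.01
    # eROHi
    erohi_threshold: float | None = None   # None -> simpleM-derived
    erohi_min_consecutive: int = 2
    # iHS / nSL
    maf_floor: float = 0.05
    bin_width: float = 0.025
    win_bp: int = 500_000
    slide_bp: int = 100_000
    outlier_neglogp: float = 2.0
    prop_threshold: float = 0.10
    # HRiD
    hrid_window_snps: int = 70
    hrid_step_snps: int = 35
    hrid_threshold: float = 3.3
    hrid_merge: bool = True
    # networks
    net_max_mutations: int = 3

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path):
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def _write_bed(intervals, path, name="signal"):
    """intervals: iterable of (start_bp, end_bp) 1-based closed."""
    with open(path, "w") as fh:
        fh.write("# BED: 0-based half-open (converted from 1-based closed)\n")
        for i, (s, e) in enumerate(intervals):
            fh.write(f"X\t{s - 1}\t{e}\t{name}_{i + 1}\n")


def prepare(gm: gio.GenotypeMatrix, config: RunConfig):
    """QC, PAR localization and hemizygous clean-up; returns the analysis-
    ready matrix plus a report dict."""
    gm_qc, qc_report = gio.qc_filter(
        gm,
        snp_call_rate=config.snp_call_rate,
        hwe_p=config.hwe_p,
        ind_call_rate=config.ind_call_rate,
        gentrain=config.gentrain,
        gencall=config.gencall,
    )
    boundary_bp, mis_ids = gio.detect_par(
        gm_qc, window_snps=config.par_window_snps, het_floor=config.par_het_floor
    )
    gm_par = gio.flag_par(gm_qc, boundary_bp)
    gm_clean, dropped = gio.clean_hemizygous(gm_par)
    gm_clean.snps = gio.assign_ancestral(gm_clean)
    report = {
        "par_boundary_bp": boundary_bp,
        "n_par_snps": int(gm_clean.snps["in_par"].sum()),
        "mis_genotyped": mis_ids,
        "qc_dropped": qc_report,
        "hemi_dropped": dropped,
    }
    return gm_clean, report


def run_scan(gm, phased, config: RunConfig, write: bool = True):
    """Run every scan on an analysis-ready dataset.

    ``gm`` must be QC'd, PAR-flagged and hemizygous-clean (see
    :func:`prepare`); ``phased`` is the (n_samples, 2, n_snps) haplotype
    array aligned to ``gm`` (male non-PAR copies duplicated).  Returns a
    result bundle dict; with ``write`` the standard TSV/BED outputs are
    written under ``config.out_prefix``.
    """
    prefix = Path(config.out_prefix)
    if write:
        prefix.parent.mkdir(parents=True, exist_ok=True)
    results = {"config": asdict(config), "config_digest": config.digest()}
    in_par = gm.snps["in_par"].to_numpy()

    # --- eROHi on diploid females (focal species) -------------------------
    females = gm.subset(sample_mask=gm.sample_mask(sex="female", species="focal"))
    segments = _erohi.call_roh(females)
    freqs = _erohi.snp_roh_frequency(segments, gm.snps, n_females=females.n_samples)
    roh_signals = []
    erohi_threshold = config.erohi_threshold
    try:
        freqs = _erohi.roh_neglogp(freqs)
        if erohi_threshold is None:
            sm = _erohi.simple_m(females)
            erohi_threshold = sm.threshold_neglogp
            results["simple_m"] = sm
        roh_signals = _erohi.call_erohi_signals(
            freqs, erohi_threshold, min_consecutive=config.erohi_min_consecutive
        )
    except ValueError:
        logger.warning("ROH frequency degenerate; skipping eROHi significance")
        freqs["z"] = np.nan
        freqs["neglogp"] = np.nan
    results["roh_segments"] = segments
    results["roh_freqs"] = freqs
    results["erohi_threshold"] = erohi_threshold
    results["erohi_signals"] = roh_signals

    # --- iHS / nSL on phased haplotypes (focal species) -------------------
    snps_anc = gm.snps
    ihs_tables, nsl_tables, ihs_windows, nsl_windows = [], [], [], []
    focal = gm.sample_mask(species="focal")
    male = gm.sample_mask(sex="male")
    for par_flag in (True, False):
        region = in_par == par_flag
        if region.sum() < 2:
            continue
        submap = snps_anc.loc[region].reset_index(drop=True)
        rows = []
        for i in np.flatnonzero(focal):
            rows.append(phased[i, 0, region])
            if par_flag or not male[i]:
                rows.append(phased[i, 1, region])
        haps = np.array(rows)
        haps, _ = gio.recode_ancestral(haps, submap)
        ihs_tables.append(hs.bin_standardize(
            hs.ihs_raw(haps, submap, maf_floor=config.maf_floor),
            bin_width=config.bin_width))
        nsl_tables.append(hs.bin_standardize(
            hs.nsl_raw(haps, submap, maf_floor=config.maf_floor),
            bin_width=config.bin_width))
    ihs_scores = pd.concat(ihs_tables).sort_values("pos_bp").reset_index(drop=True)
    nsl_scores = pd.concat(nsl_tables).sort_values("pos_bp").reset_index(drop=True)
    ihs_windows = hs.window_outlier_scan(
        ihs_scores, win_bp=config.win_bp, slide_bp=config.slide_bp,
        outlier_neglogp=config.outlier_neglogp, prop_threshold=config.prop_threshold)
    nsl_windows = hs.window_outlier_scan(
        nsl_scores, win_bp=config.win_bp, slide_bp=config.slide_bp,
        outlier_neglogp=config.outlier_neglogp, prop_threshold=config.prop_threshold)
    results["ihs_scores"], results["nsl_scores"] = ihs_scores, nsl_scores
    results["ihs_windows"], results["nsl_windows"] = ihs_windows, nsl_windows

    # --- HRiD on hemizygous male haplotypes -------------------------------
    nonpar_map = gm.snps.loc[~in_par].reset_index(drop=True)
    male_focal = gm.sample_mask(sex="male", species="focal")
    male_haps = phased[male_focal][:, 0, :][:, ~in_par]
    hrid_windows, hrid_sigs = _hrid.hrid_scan(
        male_haps, nonpar_map,
        size=config.hrid_window_snps, step=config.hrid_step_snps,
        threshold=config.hrid_threshold, merge=config.hrid_merge)
    results["hrid_windows"] = hrid_windows
    results["hrid_signals"] = hrid_sigs

    # --- median-joining networks on HRiD signals --------------------------
    networks = []
    out_male = gm.sample_mask(sex="male", species="outgroup")
    labels_focal = gm.samples.loc[male_focal, "population"].tolist()
    labels_out = gm.samples.loc[out_male, "population"].tolist()
    nonpar_idx = np.flatnonzero(~in_par)
    pos_nonpar = nonpar_map["pos_bp"].to_numpy()
    all_male_haps = np.concatenate([
        phased[male_focal][:, 0, :][:, ~in_par],
        phased[out_male][:, 0, :][:, ~in_par],
    ])
    all_labels = labels_focal + labels_out
    for sig in hrid_sigs:
        lo = int(np.searchsorted(pos_nonpar, sig.start_bp, side="left"))
        hi = int(np.searchsorted(pos_nonpar, sig.end_bp, side="right")) - 1
        nodes = hn.unique_haplotypes(all_male_haps, all_labels, window=(lo, hi))
        net = hn.median_joining_network(nodes)
        group, seeds = hn.favourable_group(net, max_mutations=config.net_max_mutations)
        try:
            origin = hn.classify_origin(net, group)
        except ValueError:
            origin = "NA"
        networks.append({"signal": sig, "network": net, "group": group,
                         "seeds": seeds, "origin": origin})
    results["networks"] = networks

    if write:
        _write_outputs(results, gm, prefix)
    return results


def _write_outputs(results, gm, prefix: Path):
    _write_tsv(_erohi.segments_frame(results["roh_segments"]), f"{prefix}.roh_segments.tsv")
    _write_tsv(results["roh_freqs"], f"{prefix}.roh_freq.tsv")
    sig_df = pd.DataFrame(
        [(s.start_bp, s.end_bp, s.n_outlier_snps, s.peak_neglogp) for s in results["erohi_signals"]],
        columns=["start_bp", "end_bp", "n_outlier_snps", "peak_neglogp"],
    )
    _write_tsv(sig_df, f"{prefix}.erohi_signals.tsv")
    _write_bed([(s.start_bp, s.end_bp) for s in results["erohi_signals"]],
               f"{prefix}.erohi_signals.bed", "eROHi")
    _write_tsv(results["ihs_scores"], f"{prefix}.ihs_scores.tsv")
    _write_tsv(results["nsl_scores"], f"{prefix}.nsl_scores.tsv")
    _write_tsv(hs.windows_frame(results["ihs_windows"]), f"{prefix}.ihs_windows.tsv")
    _write_tsv(hs.windows_frame(results["nsl_windows"]), f"{prefix}.nsl_windows.tsv")
    _write_tsv(_hrid.windows_frame(results["hrid_windows"]), f"{prefix}.hrid_windows.tsv")
    hsig_df = pd.DataFrame(
        [(s.start_bp, s.end_bp, ",".join(map(str, s.window_indices)), s.peak_hrid, s.peak_neglogp)
         for s in results["hrid_signals"]],
        columns=["start_bp", "end_bp", "windows", "peak_hrid", "peak_neglogp"],
    )
    _write_tsv(hsig_df, f"{prefix}.hrid_signals.tsv")
    _write_bed([(s.start_bp, s.end_bp) for s in results["hrid_signals"]],
               f"{prefix}.hrid_signals.bed", "HRiD")
    for k, item in enumerate(results["networks"]):
        hn.write_gml(item["network"], f"{prefix}.net{k + 1}.gml")
        _write_tsv(hn.nodes_frame(item["network"]), f"{prefix}.net{k + 1}.nodes.tsv")
        _write_tsv(hn.to_edge_list(item["network"]), f"{prefix}.net{k + 1}.edges.tsv")
    _write_tsv(manhattan_export(results, gm), f"{prefix}.manhattan.tsv")
    log = {
        "config": results["config"],
        "config_digest": results["config_digest"],
        "seed": results["config"]["seed"],
        "n_snps": int(gm.n_snps),
        "n_samples": int(gm.n_samples),
    }
    with open(f"{prefix}.runlog.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)


def manhattan_export(results, gm) -> pd.DataFrame:
    """Plot-ready long table: one row per SNP/window per scan track.

    PAR SNPs are flagged so they can be coloured separately in a Manhattan
    plot.
    """
    in_par = dict(zip(gm.snps["pos_bp"], gm.snps["in_par"]))
    rows = []
    rf = results.get("roh_freqs")
    if rf is not None and "neglogp" in rf:
        thr = results.get("erohi_threshold")
        for r in rf.itertuples(index=False):
            rows.append((int(r.pos_bp), r.neglogp, "erohi",
                         bool(thr is not None and np.isfinite(r.neglogp) and r.neglogp >= thr),
                         bool(in_par.get(int(r.pos_bp), False))))
    for track in ("ihs", "nsl"):
        df = results.get(f"{track}_scores")
        if df is None:
            continue
        for r in df.itertuples(index=False):
            rows.append((int(r.pos_bp), r.neglogp, track,
                         bool(np.isfinite(r.neglogp) and r.neglogp > 2.0),
                         bool(in_par.get(int(r.pos_bp), False))))
    for w in results.get("hrid_windows", []):
        mid = (w.start_bp + w.end_bp) // 2
        rows.append((mid, w.neglogp, "hrid", bool(w.significant), False))
    return pd.DataFrame(rows, columns=["pos_bp", "neglogp", "track", "significant", "in_par"])
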