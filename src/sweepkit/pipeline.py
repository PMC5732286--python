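"""End-to-end orchestration: QC -> structure -> differentiation -> EHH
scans -> regions -> intersection -> annotation, with every artifact
written to an output directory and a JSON run log."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import io as gio
from .differentiation import (di_track, flag_threshold, flag_top_fraction,
                              wc_fst_per_snp, window_means)
from .ehh import assign_ancestral_major, assign_ancestral_random, ihs_scan, rsb_scan
from .regions import (annotate_regions, call_runs, call_window_regions,
                      intersect_region_sets, read_gene_intervals)
from .structure import dapc, pca
from .types import regions_to_bed, regions_to_frame

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

DEFAULT_AUTOSOMES = frozenset(str(c) for c in range(1, 27))  # ovine 1-26


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class PipelineConfig:
    ped_path: str = ""
    map_path: str = ""
    vcf_path: str = ""
    samples_path: str = ""
    genes_path: str = ""
    out_dir: str = "pipeline_out"
    focal_group: str = ""               # default: first group in sample table
    autosomes: frozenset = DEFAULT_AUTOSOMES
    min_snp_call: float = 0.95
    min_sample_call: float = 0.95
    min_maf: float = 0.03
    thin_k: int = 10
    n_pcs: int | None = None
    n_axes: int | None = None
    scaling: str = "patterson"
    window: int = 20
    top_frac: float = 0.01
    di_threshold: float = 4.0
    di_mode: str = "per-snp"            # "per-snp" | "window"
    ehh_cutoff: float = 0.05
    sig_threshold: float = 4.0
    bin_width: float = 0.05
    ancestral: str = "major"            # "major" | "random"
    pad_bp: int = 500
    min_run: int = 2
    min_windows: int = 2
    seed: int = 0

    def hash(self) -> str:
        payload = {k: (sorted(v) if isinstance(v, frozenset) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    qc_reports: list = field(default_factory=list)
    pca: object = None
    dapc: object = None
    di: object = None
    ihs: object = None
    rsb: object = None
    regions: dict = field(default_factory=dict)
    overlaps: list = field(default_factory=list)
    annotation: object = None
    log: dict = field(default_factory=dict)


def _scatter(coords, labels, xlabel, ylabel, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in dict.fromkeys(labels):
        sel = np.asarray(labels, dtype=object) == lab
        ax.scatter(coords[sel, 0], coords[sel, 1] if coords.shape[1] > 1
                   else np.zeros(sel.sum()), s=8, label=str(lab))
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=6, markerscale=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage, writing artifacts under ``config.out_dir``.

    Deterministic stages are byte-identical across reruns with the same
    config; the scan seed feeds only the optional random ancestral
    assignment.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()
    log = {"config_hash": config.hash(), "seed": config.seed, "stages": []}
    t_start = time.time()

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                info = fn() or {}
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log["stages"].append({"stage": name, "seconds":
                                  round(time.time() - t0, 3), **info})
        return wrap

    state: dict = {}

    @stage("qc")
    def _qc():
        st = gio.read_sample_table(config.samples_path)
        G, mm, st = gio.read_plink_textset(config.ped_path, config.map_path,
                                           sample_table=st)
        G, st, rep_s = gio.sample_qc_filter(
            G, st, min_sample_call=config.min_sample_call)
        G, mm, rep_m = gio.snp_qc_filter(
            G, mm, min_snp_call=config.min_snp_call, min_maf=config.min_maf,
            autosomes=config.autosomes)
        rep_s.to_tsv(out / "qc_samples.tsv")
        rep_m.to_tsv(out / "qc_snps.tsv")
        res.qc_reports = [rep_s, rep_m]
        state.update(G=G, mm=mm, st=st)
        return {"n_samples": G.n_samples, "n_snps": G.n_snps}

    @stage("thin")
    def _thin():
        idx = gio.thin_every_kth(state["mm"], config.thin_k)
        state["thin_idx"] = idx
        return {"n_retained": len(idx)}

    @stage("pca_dapc")
    def _structure():
        G_thin = state["G"].take_snps(state["thin_idx"])
        p = pca(G_thin, scaling=config.scaling)
        d = dapc(G_thin, state["st"].group, n_pcs=config.n_pcs,
                 n_axes=config.n_axes, scaling=config.scaling)
        res.pca, res.dapc = p, d
        pd.DataFrame(p.coordinates[:, :10]).assign(
            sample_id=state["st"].sample_id).to_csv(
            out / "pca_coordinates.tsv", sep="\t", index=False)
        pd.DataFrame({"eigenvalue": p.eigenvalues,
                      "pct_variance": p.pct_variance}).to_csv(
            out / "pca_eigen.tsv", sep="\t", index=False)
        pd.DataFrame(d.coordinates).assign(
            sample_id=state["st"].sample_id).to_csv(
            out / "dapc_coordinates.tsv", sep="\t", index=False)
        _scatter(p.coordinates[:, :2], state["st"].population,
                 f"PC1 ({p.pct_variance[0]:.2f}%)",
                 f"PC2 ({p.pct_variance[1]:.2f}%)" if len(p.pct_variance) > 1
                 else "", out / "pca.png")
        _scatter(d.coordinates, state["st"].population, "LD1",
                 "LD2" if d.coordinates.shape[1] > 1 else "",
                 out / "dapc.png")
        return {"pc1_pct": round(float(p.pct_variance[0]), 2),
                "retained_pcs": d.retained_pc_count}

    @stage("fst_di")
    def _fst_di():
        st, mm = state["st"], state["mm"]
        focal = config.focal_group or st.group[0]
        others = [g for g in dict.fromkeys(st.group) if g != focal]
        if not others:
            raise ValueError("need >= 2 groups for differentiation")
        tracks = {f"{focal}|{g}": wc_fst_per_snp(state["G"], st.group,
                                                 focal, g) for g in others}
        di = di_track(tracks, focal)
        if config.di_mode == "window":
            wt = flag_top_fraction(window_means(di, mm, config.window),
                                   config.top_frac)
            state["di_windows"] = wt
            wt.to_tsv(out / "di_windows.tsv")
        di = flag_threshold(di, config.di_threshold)
        res.di = di
        di.to_tsv(out / "di.tsv", mm)
        return {"n_significant": int(di.flags.sum()), "focal_group": str(focal)}

    @stage("ehh_scans")
    def _ehh():
        st = gio.read_sample_table(config.samples_path)
        H, vmm, vst = gio.read_phased_vcf(config.vcf_path, sample_table=st)
        keep = np.flatnonzero(np.isin(vmm.snp_id, state["mm"].snp_id))
        H, vmm = H.take_snps(keep), vmm.take(keep)
        focal = config.focal_group or vst.group[0]
        fidx = vst.indices_of_group(focal)
        oidx = np.flatnonzero(vst.group != focal)
        H_f, H_o = H.take_samples(fidx), H.take_samples(oidx)
        if config.ancestral == "major":
            anc = assign_ancestral_major(H_f.values.mean(axis=0))
        else:
            anc = assign_ancestral_random(vmm.n_snps, config.seed)
        ihs = ihs_scan(H_f, anc, vmm, bin_width=config.bin_width,
                       threshold=config.sig_threshold,
                       cutoff=config.ehh_cutoff)
        rsb = rsb_scan(H_f, H_o, vmm, threshold=config.sig_threshold,
                       cutoff=config.ehh_cutoff)
        res.ihs, res.rsb = ihs, rsb
        state["vmm"] = vmm
        ihs.to_frame(vmm).to_csv(out / "ihs.tsv", sep="\t", index=False,
                                 na_rep="NA")
        rsb.to_frame(vmm).to_csv(out / "rsb.tsv", sep="\t", index=False,
                                 na_rep="NA")
        return {"n_ihs_significant": int(ihs.flags.sum()),
                "n_rsb_significant": int(rsb.flags.sum())}

    @stage("regions")
    def _regions():
        sets = {}
        if config.di_mode == "window" and "di_windows" in state:
            sets["di"] = call_window_regions(state["di_windows"],
                                             config.min_windows, method="di")
        else:
            sets["di"] = call_runs(res.di, state["mm"], config.min_run,
                                   config.pad_bp, method="di")
        sets["ihs"] = call_runs(res.ihs, state["vmm"], config.min_run,
                                config.pad_bp, method="ihs")
        sets["rsb"] = call_runs(res.rsb, state["vmm"], config.min_run,
                                config.pad_bp, method="rsb")
        res.regions = sets
        for name, regs in sets.items():
            regions_to_frame(regs).to_csv(out / f"regions_{name}.tsv",
                                          sep="\t", index=False)
            regions_to_bed(regs, out / f"regions_{name}.bed")
        return {f"n_{k}": len(v) for k, v in sets.items()}

    @stage("intersect")
    def _intersect():
        res.overlaps = intersect_region_sets(res.regions)
        pd.DataFrame([{
            "methods": "+".join(o.methods), "chrom": o.chrom,
            "start": o.start, "end": o.end} for o in res.overlaps]).to_csv(
            out / "overlaps.tsv", sep="\t", index=False)
        return {"n_overlaps": len(res.overlaps)}

    if config.genes_path:
        @stage("annotate")
        def _annotate():
            genes = read_gene_intervals(config.genes_path)
            all_regions = [r for regs in res.regions.values() for r in regs]
            ann = annotate_regions(all_regions, genes)
            res.annotation = ann
            ann.to_csv(out / "region_genes.tsv", sep="\t", index=False)
            return {"n_pairs": len(ann),
                    "n_distinct_genes": ann.attrs["n_distinct_genes"]}

    log["total_seconds"] = round(time.time() - t_start, 3)
    res.log = log
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return res
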