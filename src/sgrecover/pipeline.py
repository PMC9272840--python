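"""End-to-end orchestration: simulate -> callpeaks -> pars-profile -> recovery.

``run_all`` drives the full analysis from one configuration dict, writes
every stage output under an output directory and returns a run manifest:
the configuration snapshot, checksums of the generated inputs, per-stage
record counts and the headline result tables (recovery fractions, length
summaries, abundance comparison, metaprofile summary). Manifest counts
along the peak-calling cascade are checked to be non-increasing on every
run.
"""

from __future__ import annotations

import hashlib
import json
import os

import yaml

from . import __version__
from .drach import scan_drach
from .formats_io import (
    write_counts,
    write_coverage,
    write_fasta,
    write_group_list,
    write_peaks,
)
from .pars import compare_profiles, metaprofile, profile_table
from .peaks import METHYLATED, PeakParams, call_methylation, status_table
from .recovery import (
    build_pool,
    compare_abundance,
    group_lengths,
    recovery_fraction,
    recovery_table,
    rpkm,
)
from .simulate import (
    SimConfig,
    config_dict,
    control_sites,
    simulate_m6a_coverage,
    simulate_pars,
    simulate_pools,
    simulate_transcriptome,
)


def default_config(seed: int = 0) -> dict:
    """Full pipeline configuration with every published parameter surfaced."""
    return {
        "seed": seed,
        "simulate": config_dict(SimConfig(seed=seed)),
        "peaks": {
            "window_size": 50,
            "step": 25,
            "pom_threshold": 3.0,
            "min_mean_cov": 10.0,
            "epsilon": 0.1,
            "shared": "overlap",
        },
        "pars": {
            "pseudocount": 1.0,
            "half_window": 50,
            "zoom": 10,
            "statistic": "mean",
            "max_control_sites": None,
        },
        "recovery": {"min_count": 1},
        "io": {"coverage_dialect": "tsv"},
    }


def load_config(path: str) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config(user.get("seed", 0))
    for section, values in user.items():
        if isinstance(values, dict):
            cfg.setdefault(section, {}).update(values)
        else:
            cfg[section] = values
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class ManifestError(ValueError):
    """The run manifest violates its schema or cascade invariants."""


#: Structural schema for the run manifest (mirrored in docs/manifest.schema.json).
MANIFEST_SCHEMA: dict[str, type] = {
    "version": str,
    "seed": int,
    "config": dict,
    "checksums": dict,
    "peak_cascade": dict,
    "methylation": dict,
    "pools": dict,
    "recovery": list,
    "lengths": dict,
    "abundance": dict,
    "pars": dict,
}

_CASCADE_ORDER = [
    "windows_scored", "windows_retained", "windows_after_shared", "windows_drach",
]


def validate_manifest(manifest: dict) -> None:
    """Structural schema check plus the cascade-monotonicity invariant."""
    for key, typ in MANIFEST_SCHEMA.items():
        if key not in manifest:
            raise ManifestError(f"manifest missing key {key!r}")
        if not isinstance(manifest[key], typ):
            raise ManifestError(
                f"manifest[{key!r}] should be {typ.__name__}, got "
                f"{type(manifest[key]).__name__}"
            )
    cascade = manifest["peak_cascade"]
    counts = [cascade[k] for k in _CASCADE_ORDER]
    if any(a < b for a, b in zip(counts, counts[1:])):
        raise ManifestError(f"peak cascade counts increased: {dict(zip(_CASCADE_ORDER, counts))}")


def run_all(config: dict, outdir: str) -> dict:
    """Run the whole synthetic-data analysis and write outputs + manifest.

    Stage failures propagate as exceptions naming the stage. Rerunning with
    the same config (including seed) reproduces identical outputs.
    """
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    sim_cfg = SimConfig(**{**config["simulate"], "seed": seed,
                           "conditions": tuple(config["simulate"]["conditions"])})
    paths: dict[str, str] = {}

    # --- simulate -----------------------------------------------------------
    truth = simulate_transcriptome(sim_cfg)
    ip_tracks, input_tracks = simulate_m6a_coverage(sim_cfg, truth)
    pars_tracks = simulate_pars(sim_cfg, truth, config["pars"]["pseudocount"])
    pool_tables = simulate_pools(sim_cfg, truth)

    paths["fasta"] = os.path.join(outdir, "transcriptome.fa")
    write_fasta(truth.transcripts, paths["fasta"])
    paths["ip_coverage"] = os.path.join(outdir, "ip_coverage.tsv")
    write_coverage(ip_tracks, paths["ip_coverage"])
    paths["input_coverage"] = os.path.join(outdir, "input_coverage.tsv")
    write_coverage(input_tracks, paths["input_coverage"])
    for cond, table in pool_tables.items():
        paths[f"counts_{cond}"] = os.path.join(outdir, f"counts_{cond}.tsv")
        write_counts(table, paths[f"counts_{cond}"])
    write_group_list(
        {t.transcript_id: (METHYLATED if t.transcript_id in truth.methylated else "non_methylated")
         for t in truth.transcripts},
        os.path.join(outdir, "truth_groups.tsv"),
    )
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    # --- peak calling -------------------------------------------------------
    drach_index = {t.transcript_id: scan_drach(t) for t in truth.transcripts}
    params = PeakParams(**config["peaks"])
    cascade: dict[str, int] = {}
    calls = call_methylation(ip_tracks, input_tracks, drach_index, params, stats=cascade)
    all_peaks = [p for c in calls.values() for p in c.peaks]
    paths["peaks"] = os.path.join(outdir, "peaks.bed")
    write_peaks(all_peaks, paths["peaks"])
    status_table(calls).to_csv(os.path.join(outdir, "methylation_status.tsv"), sep="\t")

    called_meth = {t for t, c in calls.items() if c.status == METHYLATED}
    called_non = set(calls) - called_meth
    truth_meth = truth.methylated
    tp = len(called_meth & truth_meth)
    tn = len(called_non & truth.non_methylated)
    methylation = {
        "n_methylated": len(called_meth),
        "n_non_methylated": len(called_non),
        "sensitivity": tp / max(1, len(truth_meth)),
        "specificity": tn / max(1, len(truth.non_methylated)),
    }

    # --- PARS metaprofile ---------------------------------------------------
    pars_cfg = config["pars"]
    meth_sites = [s for c in calls.values() for p in c.peaks for s in p.drach_sites]
    # one site per transcript keeps sites independent across transcripts
    seen: set[str] = set()
    meth_sites = [s for s in meth_sites if not (s.transcript_id in seen or seen.add(s.transcript_id))]
    ctrl_sites = control_sites(sim_cfg, truth, pars_cfg["max_control_sites"])
    prof_meth = metaprofile(
        pars_tracks, meth_sites, pars_cfg["half_window"], "methylated", pars_cfg["statistic"]
    )
    prof_ctrl = metaprofile(
        pars_tracks, ctrl_sites, pars_cfg["half_window"], "unmethylated_control", pars_cfg["statistic"]
    )
    comparison = compare_profiles(prof_meth, prof_ctrl, pars_cfg["zoom"])
    profile_table(prof_meth, prof_ctrl).to_csv(os.path.join(outdir, "pars_profile.tsv"), sep="\t")
    comparison.to_csv(os.path.join(outdir, "pars_comparison.tsv"), sep="\t")
    sig = comparison["p_value"] < 0.05
    pars_summary = {
        "n_meth_sites": len(meth_sites),
        "n_ctrl_sites": len(ctrl_sites),
        "mean_meth_offset0": float(comparison.loc[0, "mean_meth"]),
        "mean_ctrl_offset0": float(comparison.loc[0, "mean_ctrl"]),
        "n_significant_offsets": int(sig.sum()),
    }

    # --- recovery -----------------------------------------------------------
    min_count = config["recovery"]["min_count"]
    results = []
    pools_summary: dict[str, int] = {}
    transcriptome = truth.transcriptome
    rpkm_groups: dict[str, list[float]] = {"methylated": [], "non_methylated": []}
    for cond, table in pool_tables.items():
        pool = build_pool(table, cond, min_count=min_count)
        pools_summary[cond] = len(pool)
        results.append(recovery_fraction(called_meth, pool, METHYLATED))
        results.append(recovery_fraction(called_non, pool, "non_methylated"))
    # abundance from the first condition's pooled counts (RPKM on the pooled library)
    first_cond = next(iter(pool_tables))
    table = pool_tables[first_cond]
    pooled = table.counts.sum(axis=1)
    lib = sum(table.library_sizes[s] for s in table.samples) // len(table.samples)
    pool0 = build_pool(table, first_cond, min_count=min_count)
    for tx_id, count in pooled.items():
        if tx_id not in pool0:
            continue
        group = "methylated" if tx_id in called_meth else "non_methylated"
        rpkm_groups[group].append(rpkm(int(count), transcriptome[tx_id].length, lib))
    abundance = compare_abundance(rpkm_groups["methylated"], rpkm_groups["non_methylated"])

    rec_df = recovery_table(results)
    rec_df.to_csv(os.path.join(outdir, "recovery.tsv"), sep="\t", index=False)
    lengths = group_lengths(
        {"methylated": called_meth, "non_methylated": called_non}, transcriptome
    )
    lengths.to_csv(os.path.join(outdir, "group_lengths.tsv"), sep="\t")

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "checksums": {name: _sha256(p) for name, p in paths.items()},
        "peak_cascade": cascade,
        "methylation": methylation,
        "pools": pools_summary,
        "recovery": rec_df.to_dict(orient="records"),
        "lengths": {
            g: {"n": int(row["n"]), "mean_length_kb": float(row["mean_length_kb"])}
            for g, row in lengths.iterrows()
        },
        "abundance": {
            "p_value": abundance["p_value"],
            "median_rpkm_methylated": abundance["median_a"],
            "median_rpkm_non_methylated": abundance["median_b"],
        },
        "pars": pars_summary,
    }
    validate_manifest(manifest)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
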