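"""Config validation and end-to-end pipeline orchestration.

One YAML config drives simulate -> count -> test -> loci/enrichment ->
profiles -> duplex -> predict -> racetails.  A single global seed yields
stage-level sub-seeds by stable hashing of stage names, so reruns with the
same config produce byte-identical result files (timestamps excluded).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import time
import yaml

from . import cleavemap, diffacc, loci as loci_mod, predict as predict_mod
from . import racetails as race_mod
from . import simdata, sio, windows as win_mod
from .duplex import fragment_energies, load_params
from .sio import ConfigurationError

log = logging.getLogger("sirspread")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {
        "n_chromosomes": 2,
        "chromosome_length": 150_000,
        "n_genes": 100,
        "gene_length": 1_200,
        "n_target_genes": 10,
        "sites_per_gene": 1,
        "mirna_length": 21,
        "site_mismatches": 0,
        "replicates": 2,
        "background_mean": 50.0,
        "dispersion": 0.1,
        "transitive_mean": 200.0,
        "fold_change": 16.0,
        "peak_halfwidth": 150,
        "frac_21": 0.8,
        "size_min": 19,
        "size_max": 26,
        "rdr6_dependence": 1.0,
        "directions": ["5p", "3p", "both"],
    },
    "windows": {"window_length": 300, "step": 150, "size_min": 19, "size_max": 26},
    "diff": {"alpha": 0.05, "adjust": "none", "min_total_count": 5,
             "normalization": "total-count", "dispersion_method": "qcml"},
    "loci": {"gap": 0},
    "profile": {"flank": 500, "min_reads": 10, "exclusivity": 0.9},
    "duplex": {"temp_c": 21.0, "allow_gu": True, "mode": "halves"},
    "predict": {"tau": 2.0, "p0": 0.5, "tau_grid": [0.0, 1.0, 2.0, 3.0]},
    "racetails": {"min_match": 20, "n_clones": 60,
                  "tail_spectrum": {"": 0.65, "U": 0.12, "UU": 0.08,
                                    "UUUU": 0.05, "A": 0.05, "AA": 0.03,
                                    "C": 0.02}},
}

STAGES = ("simulate", "windows", "diff", "loci", "profile", "duplex",
          "predict", "racetails")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigurationError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and key != "tail_spectrum":
            if not isinstance(value, dict):
                raise ConfigurationError(f"{where}: expected a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            expected = type(defaults[key])
            if expected in (int, float) and isinstance(value, (int, float)) \
                    and not isinstance(value, bool):
                out[key] = expected(value)
            elif isinstance(value, expected):
                out[key] = value
            else:
                raise ConfigurationError(
                    f"{where}: expected {expected.__name__}, "
                    f"got {type(value).__name__}")
    return out


def validate_config(path: str | os.PathLike | None = None,
                    overrides: dict | None = None) -> dict:
    """Load, merge with defaults, and validate a pipeline config.

    An empty or absent file yields pure defaults; unknown keys are errors.
    Section-level invariants are enforced by constructing each module's
    config object eagerly (validation-first).
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config root must be a mapping")
        data = loaded
    if overrides:
        data = _merge(_merge(DEFAULT_CONFIG, data), overrides)
    else:
        data = _merge(DEFAULT_CONFIG, data)

    # eager validation of every stage config
    simdata.SimConfig(seed=0, **{k: tuple(v) if k == "directions" else v
                                 for k, v in data["simulate"].items()})
    win_mod.WindowConfig(**data["windows"])
    diff = dict(data["diff"])
    diff.pop("dispersion_method")
    diffacc.DiffConfig(**diff)
    predict_mod.PredictConfig(tau=data["predict"]["tau"], p0=data["predict"]["p0"])
    if data["loci"]["gap"] < 0:
        raise ConfigurationError("loci.gap must be >= 0")
    if data["profile"]["flank"] <= 0:
        raise ConfigurationError("profile.flank must be positive")
    return data


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, outdir: str | os.PathLike) -> dict:
    """Run all stages; returns the run report (also written as MANIFEST.json).

    On stage failure, partial outputs are retained and the MANIFEST marks
    the run incomplete.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"config": config, "stages": {}, "headline": {},
                    "complete": False}
    manifest_path = os.path.join(outdir, "MANIFEST.json")

    def record(stage: str, outputs: list[str], t0: float, **extra) -> None:
        report["stages"][stage] = {
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
            "seconds": round(time.monotonic() - t0, 3),
            **extra,
        }

    try:
        state = dict(config=config, outdir=outdir)
        for stage in STAGES:
            t0 = time.monotonic()
            log.info("stage %s", stage)
            outputs, extra = _STAGE_FUNCS[stage](state)
            record(stage, outputs, t0, **extra)
        report["complete"] = True
        report["headline"] = state["headline"]
    finally:
        with open(manifest_path, "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


# ---------------------------------------------------------------------------
# stages (each takes/updates the shared state dict)
# ---------------------------------------------------------------------------

def _stage_simulate(state: dict) -> tuple[list[str], dict]:
    config, outdir = state["config"], state["outdir"]
    sim_kwargs = {k: tuple(v) if k == "directions" else v
                  for k, v in config["simulate"].items()}
    sim = simdata.SimConfig(seed=stage_seed(config["seed"], "simulate"), **sim_kwargs)
    reference, truth, mirnas = simdata.simulate_reference(sim)
    reads, library_sizes = simdata.simulate_reads(reference, truth, sim)

    genome_path = os.path.join(outdir, "genome.fa")
    gff_path = os.path.join(outdir, "genes.gff3")
    mirna_path = os.path.join(outdir, "mirnas.fa")
    sites_path = os.path.join(outdir, "target_sites.tsv")
    truth_path = os.path.join(outdir, "truth.tsv")
    aln_path = os.path.join(outdir, "alignments.tsv")
    sio.write_fasta(reference.genome, genome_path)
    sio.write_gff(reference.annotation, gff_path,
                  {c: len(s) for c, s in reference.genome.items()})
    sio.write_fasta(mirnas, mirna_path)
    sio.write_target_sites(reference.target_sites, sites_path)
    simdata.write_truth(truth, truth_path)
    all_reads = [r for sample in sorted(reads) for r in reads[sample]]
    sio.write_alignments(all_reads, aln_path)

    state.update(sim=sim, reference=reference, truth=truth, reads=reads,
                 library_sizes=library_sizes, headline={})
    return ([genome_path, gff_path, mirna_path, sites_path, truth_path,
             aln_path],
            {"n_reads": sum(library_sizes.values())})


def _stage_windows(state: dict) -> tuple[list[str], dict]:
    config, outdir = state["config"], state["outdir"]
    wconfig = win_mod.WindowConfig(**config["windows"])
    chrom_lengths = {c: len(s) for c, s in state["reference"].genome.items()}
    window_list = win_mod.make_windows(chrom_lengths, wconfig)
    all_reads = [r for sample in sorted(state["reads"])
                 for r in state["reads"][sample]]
    samples = sorted(state["reads"])
    matrix = win_mod.count_reads(all_reads, window_list, wconfig, samples=samples)
    counts_path = os.path.join(outdir, "window_counts.tsv")
    matrix.to_tsv(counts_path)
    state.update(matrix=matrix, wconfig=wconfig)
    return [counts_path], {"n_windows": len(window_list)}


def _comparison_samples(matrix, genotype: str) -> list[str]:
    return [s for s in matrix.samples if s.startswith(genotype + "_rep")]


def _stage_diff(state: dict) -> tuple[list[str], dict]:
    config, outdir = state["config"], state["outdir"]
    dconf_kwargs = dict(config["diff"])
    dispersion_method = dconf_kwargs.pop("dispersion_method")
    dconfig = diffacc.DiffConfig(**dconf_kwargs)
    matrix = state["matrix"]
    outputs = []
    results = {}
    for case, control, tag in (("ski2_RDR6", "SKI2_RDR6", "RDR6"),
                               ("ski2_rdr6", "SKI2_rdr6", "rdr6")):
        df = diffacc.test_windows(
            matrix, _comparison_samples(matrix, control),
            _comparison_samples(matrix, case), dconfig,
            dispersion_method=dispersion_method)
        path = os.path.join(outdir, f"diff_{tag}.tsv")
        df.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        results[tag] = df
    state.update(diff_results=results, dconfig=dconfig)
    n_sig = int(results["RDR6"]["significant"].sum())
    return outputs, {"n_significant_RDR6": n_sig}


def _stage_loci(state: dict) -> tuple[list[str], dict]:
    config, outdir = state["config"], state["outdir"]
    reference = state["reference"]
    merged = loci_mod.merge_windows(state["diff_results"]["RDR6"],
                                    gap=config["loci"]["gap"])
    annotated = loci_mod.annotate_loci(merged, reference.annotation,
                                       reference.target_sites)
    universe = set(reference.annotation.genes)
    targets = {ts.transcript_id for ts in reference.target_sites}
    locus_genes = {g for l in annotated if l.direction == "up_in_mutant"
                   for g in l.gene_ids}
    enr = loci_mod.enrichment_test(locus_genes, universe, targets)
    loci_path = os.path.join(outdir, "loci.tsv")
    enr_path = os.path.join(outdir, "enrichment.json")
    loci_mod.loci_to_frame(annotated).to_csv(loci_path, sep="\t", index=False)
    with open(enr_path, "w") as fh:
        json.dump({"table": enr.table, "odds_ratio": enr.odds_ratio,
                   "p_one_sided": enr.p_one_sided,
                   "p_two_sided": enr.p_two_sided}, fh, indent=2)
    state.update(loci=annotated, enrichment=enr)
    state["headline"].update(
        n_loci=len(annotated),
        n_up=sum(l.direction == "up_in_mutant" for l in annotated),
        enrichment_p=enr.p_one_sided)
    return [loci_path, enr_path], {"n_loci": len(annotated)}


def _stage_profile(state: dict) -> tuple[list[str], dict]:
    config, outdir = state["config"], state["outdir"]
    reference = state["reference"]
    pconf = config["profile"]
    mutant_samples = [s for s in state["reads"] if s.startswith("ski2_RDR6_rep")]
    pooled = [r for s in sorted(mutant_samples) for r in state["reads"][s]]
    lib = sum(state["library_sizes"][s] for s in mutant_samples)
    rows = []
    calls = {}
    profile_rows = []
    for ts in reference.target_sites:
        site = cleavemap.derive_cleavage_site(ts)
        gene = reference.annotation[ts.transcript_id]
        profile = cleavemap.build_profile(pooled, gene, site, flank=pconf["flank"])
        call = cleavemap.classify_direction(profile, min_reads=pconf["min_reads"],
                                            exclusivity=pconf["exclusivity"])
        calls[(ts.transcript_id, ts.mirna_name)] = call
        rows.append((ts.transcript_id, ts.mirna_name, site.cleavage,
                     call.n5, call.n3, call.fraction, call.call))
        pframe = cleavemap.profile_to_frame(profile, library_size=lib)
        pframe.insert(0, "transcript_id", ts.transcript_id)
        pframe.insert(1, "mirna_name", ts.mirna_name)
        profile_rows.append(pframe)
    import pandas as pd
    calls_path = os.path.join(outdir, "direction_calls.tsv")
    profile_path = os.path.join(outdir, "profiles.tsv")
    pd.DataFrame(rows, columns=["transcript_id", "mirna_name", "cleavage",
                                "n5", "n3", "fraction", "call"]
                 ).to_csv(calls_path, sep="\t", index=False)
    (pd.concat(profile_rows) if profile_rows else pd.DataFrame()
     ).to_csv(profile_path, sep="\t", index=False)
    state.update(direction_calls=calls)
    return [calls_path, profile_path], {"n_sites": len(rows)}


def _transcript_sequence(state: dict, transcript_id: str) -> str:
    gene = state["reference"].annotation[transcript_id]
    return sio.to_rna(state["reference"].genome[gene.chrom][gene.start:gene.end])


def _stage_duplex(state: dict) -> tuple[list[str], dict]:
    config, outdir = state["config"], state["outdir"]
    dconf = config["duplex"]
    params = load_params()
    temperature = dconf["temp_c"] + 273.15
    energies = {}
    rows = []
    for ts in state["reference"].target_sites:
        site = cleavemap.derive_cleavage_site(ts)
        seq = _transcript_sequence(state, ts.transcript_id)
        site_seq = seq[ts.start:ts.end]
        offset = site.cleavage - ts.start
        fe = fragment_energies(ts.mirna_sequence, site_seq, offset, params,
                               temperature, allow_gu=dconf["allow_gu"],
                               mode=dconf["mode"])
        energies[(ts.transcript_id, ts.mirna_name)] = fe
        rows.append((ts.transcript_id, ts.mirna_name, fe.dG5, fe.dG3, fe.delta))
    import pandas as pd
    path = os.path.join(outdir, "duplex_energies.tsv")
    pd.DataFrame(rows, columns=["transcript_id", "mirna_name", "dG5", "dG3",
                                "ddG"]).to_csv(path, sep="\t", index=False)
    state.update(energies=energies)
    return [path], {"n_sites": len(rows)}


def _stage_predict(state: dict) -> tuple[list[str], dict]:
    config, outdir = state["config"], state["outdir"]
    pconf = config["predict"]
    pc = predict_mod.PredictConfig(tau=pconf["tau"], p0=pconf["p0"])
    # eligibility: transcripts targeted by a single small RNA
    site_count: dict[str, int] = {}
    for ts in state["reference"].target_sites:
        site_count[ts.transcript_id] = site_count.get(ts.transcript_id, 0) + 1
    eligible = {tid for tid, n in site_count.items() if n == 1}

    energies_by_tid = {tid: fe for (tid, _), fe in state["energies"].items()
                       if tid in eligible}
    calls_by_tid = {tid: call.call
                    for (tid, _), call in state["direction_calls"].items()
                    if tid in eligible}
    predictions = {tid: predict_mod.predict_side(fe, pc)
                   for tid, fe in energies_by_tid.items()}
    k, n = predict_mod.evaluate_predictions(predictions, calls_by_tid, eligible)
    tail = predict_mod.binomial_upper_tail(k, n, pc.p0) if n else float("nan")
    grid = predict_mod.tau_sensitivity(energies_by_tid, calls_by_tid, eligible,
                                       taus=tuple(pconf["tau_grid"]), p0=pconf["p0"])

    import pandas as pd
    rows = []
    for tid in sorted(energies_by_tid):
        fe = energies_by_tid[tid]
        obs = calls_by_tid.get(tid, "none")
        pred = predictions[tid]
        rows.append((tid, fe.dG5, fe.dG3, fe.delta, pred, obs,
                     pred == obs if obs in ("five_prime", "three_prime") else ""))
    report_path = os.path.join(outdir, "prediction_report.tsv")
    summary_path = os.path.join(outdir, "prediction_summary.json")
    pd.DataFrame(rows, columns=["transcript_id", "dG5", "dG3", "ddG",
                                "predicted", "observed", "correct"]
                 ).to_csv(report_path, sep="\t", index=False)
    with open(summary_path, "w") as fh:
        json.dump({"k": k, "n": n, "p0": pc.p0, "upper_tail": tail,
                   "tau": pc.tau, "tau_grid": grid}, fh, indent=2)
    state["headline"].update(k=k, n=n, binomial_tail=tail)
    return [report_path, summary_path], {"k": k, "n": n}


def _stage_racetails(state: dict) -> tuple[list[str], dict]:
    config, outdir = state["config"], state["outdir"]
    rconf = config["racetails"]
    ts = state["reference"].target_sites[0]
    site = cleavemap.derive_cleavage_site(ts)
    transcript = _transcript_sequence(state, ts.transcript_id)
    fragment = transcript[: site.cleavage]
    downstream = transcript[site.cleavage:]
    clones, _truth = simdata.simulate_race_clones(
        fragment, rconf["n_clones"], rconf["tail_spectrum"],
        seed=stage_seed(config["seed"], "racetails"))
    fasta_path = os.path.join(outdir, "race_clones.fa")
    sio.write_fasta(clones, fasta_path)
    processed = [race_mod.extract_tail(seq, fragment, rconf["min_match"],
                                       clone_id=name,
                                       downstream_context=downstream)
                 for name, seq in clones.items()]
    summary = race_mod.summarize(processed)
    clones_path = os.path.join(outdir, "race_tails.tsv")
    summary_path = os.path.join(outdir, "race_summary.tsv")
    race_mod.clones_to_frame(processed).to_csv(clones_path, sep="\t", index=False)
    race_mod.summary_to_frame(summary).to_csv(summary_path, sep="\t", index=False)
    state["headline"].update(n_tailed=summary.n_tailed,
                             n_fragment_clones=summary.n_fragment_clones)
    return [fasta_path, clones_path, summary_path], {"n_tailed": summary.n_tailed}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "windows": _stage_windows,
    "diff": _stage_diff,
    "loci": _stage_loci,
    "profile": _stage_profile,
    "duplex": _stage_duplex,
    "predict": _stage_predict,
    "racetails": _stage_racetails,
}
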