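"""End-to-end orchestration: simulate -> callpeaks -> annotate -> kmers ->
boundaries -> splicemap (the gel-shift fit runs independently at the end).

Every stage writes TSV/JSON outputs into the run directory and the manifest
records each file with a SHA-256 checksum, so two runs of one config can be
compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import boundaries as bnd
from . import emsa, features, io, kmers, splicemap, synthetic
from .peaks import FilterConfig, call_peaks

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: dict) -> dict:
    """Execute all stages per the config; returns the run manifest."""
    out = Path(cfg["run"]["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": {}, "outputs": {}}
    files: list = []

    def record(stage, path, summary=None):
        files.append(Path(path))
        manifest["stages"].setdefault(stage, {"outputs": []})
        manifest["stages"][stage]["outputs"].append(str(path))
        if summary:
            manifest["stages"][stage].setdefault("summary", {}).update(summary)

    try:
        # --- simulate / load inputs
        sim = cfg["simulate"]
        if cfg["inputs"]["simulate"]:
            gcfg = synthetic.GenomeConfig(**sim["genome"])
            genome = synthetic.make_genome(gcfg, seed=sim["seed"])
            model = synthetic.BindingModel(**sim["binding"])
            reads, sites = synthetic.simulate_clip_reads(
                genome, model, n_reads=sim["n_reads"], seed=sim["seed"]
            )
            events = synthetic.simulate_splice_events(
                genome, n_events=sim["n_events"], seed=sim["seed"]
            )
            io.write_fasta(genome, out / "genome.fa")
            io.write_gtf(genome, out / "annotation.gtf")
            io.write_bed12(genome, out / "annotation.bed12")
            io.write_reads_bed(reads, out / "reads.bed")
            io.write_events_tsv(events, out / "events.tsv")
            for p in ("genome.fa", "annotation.gtf", "annotation.bed12",
                      "reads.bed", "events.tsv"):
                record("simulate", out / p)
            manifest["stages"]["simulate"]["summary"] = {
                "n_reads": len(reads),
                "n_sites": len(sites),
                "n_events": len(events),
                "seed": sim["seed"],
            }
        else:
            genome = io.read_genome(cfg["inputs"]["fasta"], cfg["inputs"]["gtf"])
            reads = io.read_reads_bed(cfg["inputs"]["reads"])
            events = (
                io.read_events_tsv(cfg["inputs"]["events"])
                if cfg["inputs"]["events"]
                else []
            )

        # --- peak calling
        peaks = call_peaks(reads, FilterConfig(**cfg["callpeaks"]))
        io.write_peaks(peaks, out / "peaks.tsv")
        record("callpeaks", out / "peaks.tsv", {"n_peaks": len(peaks)})

        # --- feature annotation
        index = features.build_feature_index(
            genome, promoter_width=cfg["annotate"]["promoter_width"]
        )
        assignments = features.assign_peaks(peaks, index)
        assignments, curve = features.rescue_intergenic(
            assignments, peaks, index,
            max_distance=cfg["annotate"]["rescue_distance"],
        )
        pd.DataFrame(
            [
                {
                    "peak_id": a.peak_id,
                    "category": a.category,
                    "gene_id": a.gene_id or ".",
                    "rescue_status": a.rescue_status or ".",
                    "distance_bp": a.distance_bp if a.distance_bp is not None else ".",
                }
                for a in assignments
            ]
        ).to_csv(out / "assignments.tsv", sep="\t", index=False)
        curve.to_csv(out / "rescue_curve.tsv", sep="\t", index=False)
        biotype_table = features.classify_rna_type(assignments, index)
        biotype_table.to_csv(out / "rna_types.tsv", sep="\t", index=False)
        _dump_json(
            {
                "category_proportions": features.category_proportions(assignments),
                "biotype_counts": {
                    row.biotype: int(row.n_peaks)
                    for row in biotype_table.itertuples(index=False)
                },
            },
            out / "annotation_summary.json",
        )
        for p in ("assignments.tsv", "rescue_curve.tsv", "rna_types.tsv",
                  "annotation_summary.json"):
            record("annotate", out / p)

        # --- k-mer enrichment
        kc = cfg["kmers"]
        tables = kmers.count_kmers_in_windows(
            peaks, genome, k=kc["k"], window=kc["window"], flank=kc["flank"],
            mode=kc["mode"],
        )
        background = kmers.background_frequencies(
            genome, k=kc["k"], n_shuffles=kc["shuffles"], seed=kc["seed"]
        )
        rows = []
        for region, table in tables.items():
            for s in kmers.enrichment_scores(table, background):
                rows.append(
                    {
                        "kmer": s.kmer, "region": region,
                        "count": table.counts.get(s.kmer, 0),
                        "freq": f"{s.frequency:.8g}",
                        "background_freq": f"{s.background_frequency:.8g}",
                        "score": f"{s.score:.6f}",
                    }
                )
        pd.DataFrame(rows).to_csv(out / "kmer_scores.tsv", sep="\t", index=False)
        record("kmers", out / "kmer_scores.tsv", {"k": kc["k"], "seed": kc["seed"]})

        # --- boundary metaprofiles
        bc = cfg["boundaries"]
        ei, ie = bnd.unique_boundaries(genome)
        prof_ei = bnd.profile_coverage(reads, ei)
        prof_ie = bnd.profile_coverage(reads, ie)
        bg_ei_sh, bg_ie_sh = bnd.background_profiles(
            reads, genome, "shuffle-exons", seed=bc["seed"]
        )
        bg_ei_rr, bg_ie_rr = bnd.background_profiles(
            reads, genome, "random-regions", n_regions=bc["n_regions"],
            region_length=bc["region_length"], seed=bc["seed"],
        )
        for name, prof, sh, rr in (
            ("EI", prof_ei, bg_ei_sh, bg_ei_rr),
            ("IE", prof_ie, bg_ie_sh, bg_ie_rr),
        ):
            pd.DataFrame(
                {
                    "offset": prof.offsets,
                    "count": prof.counts,
                    "n_boundaries": prof.n_boundaries,
                    "background_shuffle": sh.counts,
                    "background_shuffle_n": sh.n_boundaries,
                    "background_random": rr.counts,
                    "background_random_n": rr.n_boundaries,
                }
            ).to_csv(out / f"profile_{name}.tsv", sep="\t", index=False)
            record("boundaries", out / f"profile_{name}.tsv")

        # --- splicing map
        sc = cfg["splicemap"]
        geom = splicemap.MapGeometry(
            exon_flank=sc["exon_flank"],
            intron_window=sc["intron_window"],
            smoothing_window=sc["smoothing_window"],
        )
        classified = splicemap.classify_events(events)
        by_class = {}
        for ev in classified:
            by_class.setdefault(ev.event_class, []).append(ev)
        background_events = by_class.get("background", [])
        map_rows = []
        for cls in ("enhanced", "silenced"):
            if not by_class.get(cls) or not background_events:
                continue
            pm = splicemap.positional_density(peaks, by_class[cls], geom)
            pm = splicemap.map_significance(
                pm, background_events, peaks,
                n_permutations=sc["n_permutations"], seed=sc["seed"],
            )
            for region in splicemap.REGION_NAMES:
                for j in range(geom.region_length):
                    map_rows.append(
                        {
                            "region": region, "offset": j, "class": cls,
                            "density": f"{pm.density[region][j]:.8g}",
                            "p_value": f"{pm.p_values[region][j]:.8g}",
                        }
                    )
        pd.DataFrame(
            map_rows, columns=["region", "offset", "class", "density", "p_value"]
        ).to_csv(out / "splicing_map.tsv", sep="\t", index=False)
        record(
            "splicemap", out / "splicing_map.tsv",
            {cls: len(evs) for cls, evs in by_class.items()},
        )

        # --- gel-shift demonstration fit (independent stage)
        ec = cfg["emsa"]
        series = synthetic.simulate_titration(
            n_true=ec["n_true"], K_true=ec["K_true"], noise_sd=ec["noise_sd"],
            seed=ec["seed"],
        )
        io.write_titration_tsv(series, out / "titration.tsv")
        fit = emsa.fit_stoichiometry_affinity(series)
        _dump_json(
            {
                "n": fit.n, "ln_Kn": fit.ln_Kn, "K_per_M": fit.K,
                "se_n": fit.se_n, "se_ln_Kn": fit.se_ln_Kn,
                "r_squared": fit.r_squared, "n_points_used": fit.n_points_used,
            },
            out / "emsa_fit.json",
        )
        record("emsa", out / "titration.tsv")
        record("emsa", out / "emsa_fit.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest["outputs"] = {str(p): _sha256(p) for p in sorted(set(files))}
    _dump_json(manifest, out / "manifest.json")
    return manifest
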