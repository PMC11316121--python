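"""End-to-end demo pipeline: simulate -> phase -> screen -> enrich ->
spectrum -> report, with a machine-readable run manifest.

Each stage writes its artifacts under the output directory and records its
headline counts in the manifest; any stage failure aborts the run with the
failing stage named. All randomness derives from the single run seed, so a
re-run with the same seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

from . import io as pio
from .cohort_table import parse_cohort_table, summarize_cohort
from .enrichment import TermAnnotation, enrich
from .models import ValidationError
from .phasing import read_phase
from .screen import discovery_lof_genes, exclusion_screen, screen_cohort
from .simulate import (
    SimConfig,
    make_toy_genome,
    simulate_cohort,
    simulate_fragments,
    simulate_smallrna_sample,
)
from .spectrum import (
    SpectrumConfig,
    align_reads,
    assign_to_pirna_loci,
    compare_case_control,
    length_filter,
    length_spectrum,
    spikein_qc,
    subtract_known_sncrna,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    out_dir: Path | str,
    seed: int = 0,
    sim: Optional[SimConfig] = None,
    n_samples_per_group: int = 3,
) -> dict:
    """Run the six demo stages and return (and write) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = sim or SimConfig(seed=seed)
    manifest: dict = {"seed": seed, "stages": []}

    def stage(name: str):
        def wrap(fn):
            try:
                counts = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, exc) from exc
            manifest["stages"].append({"name": name, "status": "ok", "counts": counts})
        return wrap

    state: dict = {}

    @stage("simulate")
    def _simulate():
        cohort = simulate_cohort(sim)
        assets = make_toy_genome(sim)
        state["cohort"] = cohort
        state["assets"] = assets
        pio.write_variant_calls_tsv(out / "cohort_calls.tsv", cohort.calls)
        pio.write_gene_panel(out / "panel.txt", cohort.panel)
        pio.write_fasta(out / "toy_genome.fasta", dict(assets.reference))
        pio.write_bed(out / "pirna_loci.bed", assets.loci)
        pio.write_bed(out / "sncrna_blacklist.bed", assets.blacklist)
        samples = []
        for group in ("control", "case"):
            for i in range(n_samples_per_group):
                sample_seed = seed * 1000 + i + (0 if group == "control" else 500)
                reads, _ = simulate_smallrna_sample(
                    group, sim, assets, seed=sample_seed, sample_id=f"{group}{i+1}"
                )
                pio.write_fastq(out / f"reads_{group}{i+1}.fastq", reads)
                samples.append((f"{group}{i+1}", group, reads))
        state["samples"] = samples
        return {
            "patients": sim.n_patients,
            "variants": len(cohort.variants),
            "smallrna_samples": len(samples),
        }

    @stage("phase")
    def _phase():
        cohort = state["cohort"]
        derived = {}
        recovered = 0
        for i, (pair, planted) in enumerate(sorted(cohort.phase_calls.items())):
            frags = simulate_fragments(
                planted.configuration, n_fragments=12, seed=seed * 100 + i
            )
            call = read_phase(frags)
            derived[pair] = call
            if call.configuration == planted.configuration:
                recovered += 1
        state["phase_calls"] = derived
        return {"pairs": len(derived), "recovered": recovered}

    @stage("screen")
    def _screen():
        cohort = state["cohort"]
        result = screen_cohort(
            cohort.variants, cohort.calls, cohort.panel,
            phase_calls=state["phase_calls"],
        )
        pio.write_candidates_tsv(out / "candidates.tsv", result.confirmed)
        pio.write_candidates_json(out / "candidates.json", result.confirmed)
        pio.write_candidates_tsv(out / "candidates_unphased.tsv", result.unphased)
        by_patient: dict[str, list] = {}
        for call in cohort.calls:
            by_patient.setdefault(call.patient, []).append(call)
        with open(out / "exclusion_report.tsv", "w") as handle:
            handle.write("patient\tdecision\treasons\n")
            n_excluded = 0
            for patient in sorted({c.patient for c in result.confirmed}):
                decision = exclusion_screen(by_patient[patient], cohort.exclusion_panels)
                n_excluded += decision.decision == "exclude"
                handle.write(
                    f"{patient}\t{decision.decision}\t{';'.join(decision.reasons)}\n"
                )
        state["screen"] = result
        return {
            "confirmed": len(result.confirmed),
            "unphased": len(result.unphased),
            "excluded_secondary": n_excluded,
        }

    @stage("enrich")
    def _enrich():
        cohort = state["cohort"]
        query = discovery_lof_genes(
            cohort.variants, cohort.calls, cohort.testis_genes
        )
        panel_genes = frozenset(cohort.panel.genes)
        universe = panel_genes | cohort.testis_genes | frozenset(
            f"DECOY{i}" for i in range(60)
        )
        annotations = [
            TermAnnotation("TERM:0001", panel_genes, "piRNA processing"),
            TermAnnotation(
                "TERM:0002", frozenset(f"DECOY{i}" for i in range(0, 30)), "decoy process A"
            ),
            TermAnnotation(
                "TERM:0003", frozenset(f"DECOY{i}" for i in range(30, 60)), "decoy process B"
            ),
        ]
        results = enrich(query, annotations, universe=universe)
        pio.write_enrichment_tsv(out / "enrichment.tsv", results)
        return {
            "query_genes": len(query),
            "terms": len(results),
            "significant": sum(r.significant for r in results),
        }

    @stage("spectrum")
    def _spectrum():
        assets = state["assets"]
        cfg = SpectrumConfig()
        spectra = []
        qc = {}
        for sample_id, group, reads in state["samples"]:
            passed, counts = spikein_qc(reads, assets.spikes)
            qc[sample_id] = {"pass": passed, "counts": counts}
            retained = length_filter(reads, cfg)
            placements, _stats = align_reads(retained, assets.reference)
            kept = subtract_known_sncrna(placements, assets.blacklist, cfg)
            assigned, _per_locus = assign_to_pirna_loci(kept, assets.loci, cfg)
            spectra.append(
                length_spectrum(sample_id, group, assigned, len(retained), cfg)
            )
        comparison = compare_case_control(spectra, cfg)
        pio.write_spectra_tsv(out / "spectra.tsv", spectra)
        pio.write_comparison_json(out / "comparison.json", comparison)
        with open(out / "spikein_qc.json", "w") as handle:
            json.dump(qc, handle, indent=2)
            handle.write("\n")
        return {
            "samples": len(spectra),
            "p_two_sided": comparison.p_two_sided,
            "spike_qc_pass": sum(v["pass"] for v in qc.values()),
        }

    @stage("report")
    def _report():
        rows = parse_cohort_table()
        summary = summarize_cohort(rows)
        with open(out / "cohort_summary.json", "w") as handle:
            json.dump(dataclasses.asdict(summary), handle, indent=2)
            handle.write("\n")
        return {
            "patients": summary.n_patients,
            "genes": summary.n_genes,
            "distinct_variants": summary.n_distinct_variants,
        }

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)
        handle.write("\n")
    return manifest
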