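"""End-to-end orchestration: call -> diversity -> AMOVA -> network.

``run_study_analysis`` runs the full analysis from an aligned FASTA,
a metadata TSV and a haplotype-profile catalog, writing:

* ``assignments.tsv`` — per-sample haplotype calls;
* ``frequencies.tsv`` — per-haplotype counts, frequencies and s.d.;
* ``diversity.tsv`` — gene diversity (overall, per region, per area with
  n >= 2) and overall nucleotide diversity;
* ``polymorphism.tsv`` — polymorphic-site counts by substitution class;
* ``amova_region.tsv/.json`` — two-region AMOVA, identity distances;
* ``amova_eastern_areas.tsv/.json`` — among-area AMOVA within the eastern
  region, pairwise-difference distances (areas with fewer than two samples
  are excluded with a warning, as a single sample would skew the result);
* ``distances.tsv`` — within-population mean pairwise differences and
  between-population pi / Nei's d, both distance modes;
* ``network_edges.tsv`` — median-joining network edge list;
* ``manifest.json`` — seed, configuration and per-output SHA-256 checksums.

Human-readable tables round to 4 decimals (2–3 for the AMOVA display);
the JSON files carry full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .amova import amova_one_level, permutation_test
from .diversity import (
    gene_diversity,
    haplotype_frequencies,
    mean_pairwise_within,
    neis_distance,
    mean_pairwise_between,
    nucleotide_diversity,
    pairwise_difference_matrix,
)
from .haplotyping import call_haplotypes, summarize_polymorphisms
from .io import (
    read_alignment,
    read_profile_table,
    read_sample_metadata,
    write_profile_table,
)
from .mjnetwork import export_network, median_joining_network

logger = logging.getLogger("mthaplostat")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {error}")


@dataclass
class RunConfig:
    fasta: str
    metadata: str
    catalog: str
    outdir: str
    group_by: str = "region"
    region_distance_mode: str = "identity"
    area_distance_mode: str = "pairwise_differences"
    permutations: int = 1000
    seed: int = 0
    min_population_size: int = 2

    def validate(self) -> None:
        for label in ("fasta", "metadata", "catalog"):
            path = Path(getattr(self, label))
            if not path.exists():
                raise FileNotFoundError(f"{label} path does not exist: {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _amova_frame(result, decimals: int = 3) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source": "Among Populations",
                "df": result.df_among,
                "sum_of_squares": round(result.ssd_among, decimals),
                "variance_component": round(result.va, 5),
                "percent_variation": round(result.percent_among, 2),
                "p_value": result.p_value,
            },
            {
                "source": "Within Populations",
                "df": result.df_within,
                "sum_of_squares": round(result.ssd_within, decimals),
                "variance_component": round(result.vb, 5),
                "percent_variation": round(result.percent_within, 2),
                "p_value": result.p_value,
            },
            {
                "source": "Total",
                "df": result.df_among + result.df_within,
                "sum_of_squares": round(result.ssd_total, decimals),
                "variance_component": round(result.va + result.vb, 5),
                "percent_variation": 100.0,
                "p_value": None,
            },
        ]
    )


def run_study_analysis(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s", name)

    # ---- haplotype calling -------------------------------------------------
    try:
        stage("call")
        aln = read_alignment(config.fasta)
        meta = read_sample_metadata(config.metadata)
        catalog = read_profile_table(config.catalog)
        assignments, updated_catalog = call_haplotypes(aln, catalog)
        calls = pd.DataFrame([asdict(a) for a in assignments])
        path = outdir / "assignments.tsv"
        calls.to_csv(path, sep="\t", index=False)
        outputs["assignments"] = path
        path = outdir / "catalog_updated.tsv"
        write_profile_table(updated_catalog, path)
        outputs["catalog"] = path
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        raise PipelineError("call", exc) from exc

    hap_of = dict(zip(calls["sample_id"], calls["haplotype"]))
    members = [hap_of[s] for s in meta.sample_ids]
    area_of = meta.group_of("area")
    region_of = meta.group_of("region")

    # ---- frequencies, polymorphism and diversity ---------------------------
    try:
        stage("diversity")
        observed = [h for h in updated_catalog.names if h in set(members)]
        counts = Counter(members)
        freq = haplotype_frequencies({h: counts[h] for h in observed})
        path = outdir / "frequencies.tsv"
        freq.to_frame().to_csv(path, sep="\t", index=False)
        outputs["frequencies"] = path

        study_catalog = updated_catalog.subset(observed)
        poly = summarize_polymorphisms(study_catalog)
        path = outdir / "polymorphism.tsv"
        pd.DataFrame(
            [
                {
                    "polymorphic_sites": poly.n_sites,
                    "transitions": poly.n_transitions,
                    "transversions": poly.n_transversions,
                    "indels": poly.n_indels,
                }
            ]
        ).to_csv(path, sep="\t", index=False)
        outputs["polymorphism"] = path

        pools: dict[str, list[str]] = {"all": members}
        for sid, hap in zip(meta.sample_ids, members):
            pools.setdefault(f"region:{region_of[sid]}", []).append(hap)
            pools.setdefault(f"area:{area_of[sid]}", []).append(hap)
        pairdiff = pairwise_difference_matrix(updated_catalog, "pairwise_differences")
        rows = []
        for label, pool in pools.items():
            if len(pool) < 2:
                logger.warning("skipping %s: fewer than 2 samples", label)
                continue
            res = gene_diversity(Counter(pool))
            rows.append(
                {
                    "pool": label,
                    "n": res.n,
                    "gene_diversity": round(res.h, 4),
                    "sd": round(res.sd, 4),
                    "nucleotide_diversity": round(
                        nucleotide_diversity(pool, pairdiff, aln.n_columns), 6
                    ),
                }
            )
        path = outdir / "diversity.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        outputs["diversity"] = path
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("diversity", exc) from exc

    # ---- AMOVA -------------------------------------------------------------
    amova_json: dict[str, dict] = {}
    try:
        stage("amova")
        identity = pairwise_difference_matrix(updated_catalog, "identity")
        matrices = {"identity": identity, "pairwise_differences": pairdiff}

        region_labels = [region_of[s] for s in meta.sample_ids]
        res = amova_one_level(members, region_labels, matrices[config.region_distance_mode])
        p = permutation_test(
            res, members, region_labels, matrices[config.region_distance_mode],
            permutations=config.permutations, seed=config.seed,
        )
        res = type(res)(**{**asdict(res), "p_value": p})
        path = outdir / "amova_region.tsv"
        _amova_frame(res).to_csv(path, sep="\t", index=False)
        outputs["amova_region"] = path
        amova_json["region"] = asdict(res)

        for offset, region_name in enumerate(sorted(set(region_of.values())), 1):
            pool = [s for s in meta.sample_ids if region_of[s] == region_name]
            area_counts = Counter(area_of[s] for s in pool)
            kept = [
                s for s in pool
                if area_counts[area_of[s]] >= config.min_population_size
            ]
            dropped = sorted(
                a for a, c in area_counts.items()
                if c < config.min_population_size
            )
            if dropped:
                warnings.warn(
                    f"area(s) {dropped} excluded from the among-area AMOVA "
                    f"within the {region_name} region: a single sample would "
                    "skew the result",
                    stacklevel=2,
                )
            if len({area_of[s] for s in kept}) < 2:
                logger.info(
                    "among-area AMOVA skipped for %s: fewer than 2 usable areas",
                    region_name,
                )
                continue
            res_a = amova_one_level(
                [hap_of[s] for s in kept],
                [area_of[s] for s in kept],
                matrices[config.area_distance_mode],
            )
            p_a = permutation_test(
                res_a,
                [hap_of[s] for s in kept],
                [area_of[s] for s in kept],
                matrices[config.area_distance_mode],
                permutations=config.permutations,
                seed=config.seed + offset,
            )
            res_a = type(res_a)(**{**asdict(res_a), "p_value": p_a})
            path = outdir / f"amova_{region_name}_areas.tsv"
            _amova_frame(res_a).to_csv(path, sep="\t", index=False)
            outputs[f"amova_{region_name}_areas"] = path
            amova_json[f"{region_name}_areas"] = asdict(res_a)
        path = outdir / "amova.json"
        path.write_text(json.dumps(amova_json, indent=2) + "\n")
        outputs["amova_json"] = path
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("amova", exc) from exc

    # ---- within/between distance summaries ---------------------------------
    try:
        stage("distances")
        by_area: dict[str, list[str]] = {}
        for sid, hap in zip(meta.sample_ids, members):
            by_area.setdefault(area_of[sid], []).append(hap)
        rows = []
        for mode, matrix in matrices.items():
            areas = sorted(a for a in by_area if len(by_area[a]) >= 2)
            for a in areas:
                rows.append(
                    {
                        "mode": mode,
                        "pop_a": a,
                        "pop_b": a,
                        "statistic": "pi_within",
                        "value": round(mean_pairwise_within(by_area[a], matrix), 4),
                    }
                )
            for i, a in enumerate(areas):
                for b in areas[i + 1:]:
                    rows.append(
                        {
                            "mode": mode,
                            "pop_a": a,
                            "pop_b": b,
                            "statistic": "pi_between",
                            "value": round(
                                mean_pairwise_between(by_area[a], by_area[b], matrix), 4
                            ),
                        }
                    )
                    rows.append(
                        {
                            "mode": mode,
                            "pop_a": a,
                            "pop_b": b,
                            "statistic": "nei_d",
                            "value": round(
                                neis_distance(by_area[a], by_area[b], matrix), 4
                            ),
                        }
                    )
        path = outdir / "distances.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        outputs["distances"] = path
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("distances", exc) from exc

    # ---- median-joining network --------------------------------------------
    try:
        stage("network")
        shares: dict[str, dict[str, float]] = {}
        for hap in set(members):
            regions = Counter(
                region_of[s] for s in meta.sample_ids if hap_of[s] == hap
            )
            total = sum(regions.values())
            shares[hap] = {r: c / total for r, c in regions.items()}
        graph = median_joining_network(
            updated_catalog, counts=dict(Counter(members)), region_shares=shares
        )
        path = outdir / "network_edges.tsv"
        export_network(graph, path, fmt="tsv")
        outputs["network"] = path
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("network", exc) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_samples": len(meta),
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in outputs.items()
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
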