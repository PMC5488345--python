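"""Stage composition: catalogue -> deletion scan -> TSD calls -> classification.

Thin orchestration over the stage modules so the command-line interface,
the tests and the reproduction script all run the identical workflow.
Every function is deterministic given its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Sequence

from . import genome_io
from .genome_io import GenomeAccessor, RepeatRecord, VariantRecord
from .hml2_catalog import CatalogConfig, build_catalog, count_autosomal_ltrs, select_hml2_ltrs
from .indel_scan import ScanConfig, classify_all, filter_variants, match_deletions
from .tsd_caller import TsdConfig, call_all

__all__ = ["PipelineResult", "run_pipeline", "config_hash"]


def config_hash(*configs) -> str:
    """Short stable digest of the configuration actually used for a run."""
    blob = json.dumps([asdict(c) for c in configs], sort_keys=True, default=sorted)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class PipelineResult:
    catalog: tuple
    tsd_calls: tuple
    candidates: tuple
    summary: dict


def run_pipeline(genome: GenomeAccessor,
                 repeats: Sequence[RepeatRecord],
                 variants: Sequence[VariantRecord],
                 catalog_config: CatalogConfig = CatalogConfig(),
                 scan_config: ScanConfig = ScanConfig(),
                 tsd_config: TsdConfig = TsdConfig(),
                 skip_flagged: bool = False,
                 autosomes_only: bool = False) -> PipelineResult:
    """Run the full two-stage analysis over in-memory inputs."""
    catalog = build_catalog(repeats, catalog_config)
    if autosomes_only:
        catalog = [l for l in catalog if genome_io.is_autosome(l.chrom)]
    tsd_calls = call_all(genome, catalog, tsd_config, skip_flagged=skip_flagged)
    kept = filter_variants(variants, scan_config)
    candidates = match_deletions(catalog, kept, scan_config)
    candidates = classify_all(candidates, catalog, tsd_calls, scan_config)
    ltrs = select_hml2_ltrs(repeats, catalog_config)
    summary = {
        "config_hash": config_hash(catalog_config, scan_config, tsd_config),
        "n_repeat_records": len(list(repeats)),
        "n_selected_ltrs": len(ltrs),
        "n_autosomal_ltrs": count_autosomal_ltrs(ltrs),
        "n_loci": len(catalog),
        "n_loci_by_structure": {
            s: sum(1 for l in catalog if l.structure == s)
            for s in ("solo_ltr", "provirus", "truncated_provirus")
        },
        "n_variants_in": len(list(variants)),
        "n_variants_deletion_type": len(kept),
        "n_candidates": len(candidates),
        "n_candidates_by_status": {
            s: sum(1 for c in candidates if c.status == s)
            for s in ("preintegration_consistent", "regional_indel", "ambiguous")
        },
        "n_tsd_calls": len(tsd_calls),
    }
    return PipelineResult(catalog=tuple(catalog), tsd_calls=tuple(tsd_calls),
                          candidates=tuple(candidates), summary=summary)
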