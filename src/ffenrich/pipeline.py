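"""End-to-end screening pipelines: ordinary and size-enriched.

Stage order per sample: read filters -> (in-silico size selection or bead
simulation, in enriched mode) -> binned counting -> GC correction against
the protocol-matched reference run -> fetal-fraction estimation -> z-scores
against the protocol-matched euploid reference -> decision.  Enriched
libraries are always scored against an enriched-library reference: size
selection shifts every chromosome ratio slightly, so mixing protocols would
bias the reference mean.

The minimum-read QC is expressed per genome equivalent: ``min_reads_equiv``
(default 3.5 million, the platform's read count on the full human genome) is
scaled by the genome model's share of the full genome, so desk-scale genomes
keep the same QC meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import (CallResult, ReferenceStats, Thresholds, build_reference,
                      call_sample)
from .fetal_fraction import (ChrYCalibration, SizeFFModel, ff_from_chry,
                             estimate_ff_size_from_records)
from .filters import apply_read_filters
from .gc_normalize import (RunMedians, bin_counts, compute_run_medians,
                           gc_correct_against, _apply_steps_2_3)
from .genome import HG19_TOTAL, GenomeModel
from .simulate import BeadRetention, simulate_bead_enrichment
from .size_select import in_silico_size_select


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and protocol switches for a screening run."""

    genome: GenomeModel
    size_cutoff: int = 160
    z_cutoff: float = 3.0
    ff_floor: float = 0.04
    pdiff_ceiling: float = 0.40
    min_reads_equiv: float = 3_500_000.0
    min_length: int = 50
    bead_preset: str | None = None   # None -> hard in-silico cutoff
    min_run: int = 8
    min_reference: int = 20
    span: float = 0.75
    ff_method: str = "chry"          # "chry" | "size"

    @property
    def min_reads(self) -> float:
        """Read-count QC floor scaled to the genome model's size."""
        return self.min_reads_equiv * self.genome.total_length / HG19_TOTAL

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(z_cutoff=self.z_cutoff, min_ff=self.ff_floor,
                          min_reads=self.min_reads)


@dataclass
class Reference:
    """Protocol-matched reference: euploid ratio stats plus run medians."""

    stats: ReferenceStats
    medians: RunMedians
    mode: str


class NIPSPipeline:
    """Screening pipeline holding a config, calibrations and references."""

    def __init__(
        self,
        config: PipelineConfig,
        chry_calibration: ChrYCalibration,
        size_model: SizeFFModel | None = None,
        enrich_seed: int = 0,
    ) -> None:
        self.config = config
        self.chry_calibration = chry_calibration
        self.size_model = size_model
        self.references: dict[str, Reference] = {}
        self._enrich_rng = np.random.default_rng(enrich_seed)

    # ------------------------------------------------------------------
    def _prepare(self, records: pd.DataFrame, mode: str) -> pd.DataFrame:
        """Filter and, in enriched mode, size-select a raw fragment table."""
        if mode not in ("ordinary", "enriched"):
            raise ValueError("mode must be 'ordinary' or 'enriched'")
        filtered, _ = apply_read_filters(records, self.config.min_length)
        if mode == "enriched":
            if self.config.bead_preset is not None:
                filtered = simulate_bead_enrichment(
                    filtered, BeadRetention.preset(self.config.bead_preset),
                    rng=self._enrich_rng,
                )
            else:
                filtered = in_silico_size_select(filtered, self.config.size_cutoff)
        return filtered

    def build_reference(self, euploid_records: list[pd.DataFrame],
                        mode: str) -> Reference:
        """Build and store the euploid reference for one protocol mode."""
        tables = [
            bin_counts(self._prepare(r, mode), self.config.genome)
            for r in euploid_records
        ]
        step1, medians = compute_run_medians(
            tables, span=self.config.span, min_run=self.config.min_run
        )
        corrected = [
            _apply_steps_2_3(t, c1, m, medians)
            for t, (c1, m) in zip(tables, step1)
        ]
        stats = build_reference(corrected,
                                min_samples=self.config.min_reference)
        ref = Reference(stats=stats, medians=medians, mode=mode)
        self.references[mode] = ref
        return ref

    def estimate_ff(self, prepared: pd.DataFrame):
        if self.config.ff_method == "size":
            if self.size_model is None:
                raise ValueError("size-based fetal fraction requires a trained "
                                 "size model")
            return estimate_ff_size_from_records(
                self.size_model, prepared, self.config.pdiff_ceiling
            )
        return ff_from_chry(prepared, self.chry_calibration)

    def process(self, records: pd.DataFrame, mode: str,
                sample_id: str | None = None) -> CallResult:
        """Run one sample through the pipeline in the given mode."""
        ref = self.references.get(mode)
        if ref is None:
            raise ValueError(
                f"no {mode!r} reference available; call "
                f"build_reference(euploid_records, mode={mode!r}) first"
            )
        prepared = self._prepare(records, mode)
        ff = self.estimate_ff(prepared)
        table = bin_counts(prepared, self.config.genome, sample_id=sample_id)
        corrected = gc_correct_against(table, ref.medians, span=self.config.span)
        return call_sample(corrected, ref.stats, ff,
                           thresholds=self.config.thresholds,
                           sample_id=sample_id)

    def process_artifacts(self, records: pd.DataFrame, mode: str,
                          sample_id: str | None = None):
        """Like :meth:`process` but also returns the corrected bin table and FF."""
        ref = self.references[mode]
        prepared = self._prepare(records, mode)
        ff = self.estimate_ff(prepared)
        table = bin_counts(prepared, self.config.genome, sample_id=sample_id)
        corrected = gc_correct_against(table, ref.medians, span=self.config.span)
        call = call_sample(corrected, ref.stats, ff,
                           thresholds=self.config.thresholds,
                           sample_id=sample_id)
        return call, corrected, ff
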