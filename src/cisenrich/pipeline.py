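"""End-to-end orchestration with cross-configuration caching.

A :class:`Pipeline` holds the inputs (genome, gene table, motifs, optional
ChIP and accessibility tracks, optional multi-species profiles) and caches
every expensive intermediate — window tiling, G/C content, background
model, raw window scores, normalized profiles and region assignments — so
that running many configurations only recomputes the stages whose options
actually changed.  The final Fisher tests are cheap and always run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from collections import Counter

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfiguration
from .enrichment import EnrichmentResult, fisher_enrichment, rank_and_threshold
from .io import (GenomeSequences, MotifMatrix, SignalTrack, results_to_frame,
                 write_reports)
from .regions import assign_windows, build_target_set, define_regions, score_genes
from .scoring import ScoredMotif, score_genome, train_background
from .transforms import (NormalizedProfile, PhyloWeights, accessibility_filter,
                         gc_rank_normalize, phylo_average, rank_normalize)
from .windows import ScoreProfile, WindowSet, compute_gc, signal_to_windows, tile_windows

log = logging.getLogger(__name__)


class Pipeline:
    """Holds inputs and caches; run one or many configurations against it."""

    def __init__(self, genome: GenomeSequences, genes: pd.DataFrame,
                 motifs: list[MotifMatrix] | None = None,
                 chip_tracks: dict[str, SignalTrack] | None = None,
                 accessibility: SignalTrack | None = None,
                 phylo_weights: PhyloWeights | None = None,
                 species_profiles: dict[str, dict[str, np.ndarray]] | None = None,
                 window_length: int = 500, shift: int = 250,
                 bg_order: int = 2, pseudocount: float = 0.5):
        self.genome = genome
        self.genes = genes
        self.motifs = motifs or []
        self.chip_tracks = chip_tracks or {}
        self.accessibility = accessibility
        self.phylo_weights = phylo_weights
        # species_profiles: feature_id -> species -> per-window raw values
        # (NaN where the species has no orthologous window)
        self.species_profiles = species_profiles or {}
        self.window_length = window_length
        self.shift = shift
        self.bg_order = bg_order
        self.pseudocount = pseudocount
        self.cache_stats: Counter = Counter()
        self._windows: WindowSet | None = None
        self._gc: np.ndarray | None = None
        self._bg = None
        self._raw: dict[str, ScoreProfile] = {}
        self._averaged: dict[str, ScoreProfile] = {}
        self._norm: dict[tuple, NormalizedProfile] = {}
        self._access_profile: ScoreProfile | None = None
        self._assignments: dict[tuple, dict[str, np.ndarray]] = {}

    # ---- cached intermediates -------------------------------------------

    @property
    def windows(self) -> WindowSet:
        if self._windows is None:
            self._windows = tile_windows(self.genome.lengths,
                                         self.window_length, self.shift)
            log.info("tiled %d windows (%d bp, shift %d)",
                     len(self._windows), self.window_length, self.shift)
        return self._windows

    @property
    def gc(self) -> np.ndarray:
        if self._gc is None:
            self._gc, _ = compute_gc(self.windows, self.genome)
        return self._gc

    @property
    def background(self):
        if self._bg is None:
            self._bg = train_background(self.genome, self.bg_order)
        return self._bg

    @property
    def feature_ids(self) -> list[str]:
        return [m.motif_id for m in self.motifs] + list(self.chip_tracks)

    def raw_profile(self, feature_id: str) -> ScoreProfile:
        if feature_id in self._raw:
            self.cache_stats["raw_hit"] += 1
            return self._raw[feature_id]
        self.cache_stats["raw_miss"] += 1
        t0 = time.perf_counter()
        motif = next((m for m in self.motifs if m.motif_id == feature_id), None)
        if motif is not None:
            prof = score_genome(self.genome, self.windows,
                                ScoredMotif.from_counts(motif, self.pseudocount),
                                self.background)
        elif feature_id in self.chip_tracks:
            prof = signal_to_windows(self.chip_tracks[feature_id],
                                     self.windows, feature_id, kind="chip")
        else:
            raise KeyError(f"unknown feature {feature_id!r}")
        log.info("scored %r over %d windows in %.2fs", feature_id,
                 len(prof), time.perf_counter() - t0)
        self._raw[feature_id] = prof
        return prof

    def averaged_profile(self, feature_id: str) -> ScoreProfile:
        """Phylogenetically weighted multi-species average of raw scores."""
        if feature_id in self._averaged:
            self.cache_stats["avg_hit"] += 1
            return self._averaged[feature_id]
        if self.phylo_weights is None:
            raise ValueError("conservation requested without a species tree")
        if feature_id not in self.species_profiles:
            raise ValueError(
                f"conservation requested but no multi-species profiles for "
                f"{feature_id!r}")
        ref = self.raw_profile(feature_id)
        profs = {self.phylo_weights.reference: ref}
        for sp, vals in self.species_profiles[feature_id].items():
            profs[sp] = ScoreProfile(feature_id, np.asarray(vals, dtype=float),
                                     ref.scorable, kind=ref.kind)
        out = phylo_average(profs, self.phylo_weights)
        self._averaged[feature_id] = out
        return out

    def access_profile(self) -> ScoreProfile:
        if self.accessibility is None:
            raise ValueError("accessibility filter requested without a track")
        if self._access_profile is None:
            self._access_profile = signal_to_windows(
                self.accessibility, self.windows, "accessibility",
                kind="accessibility")
        return self._access_profile

    def normalized_profile(self, feature_id: str,
                           config: RunConfiguration) -> NormalizedProfile:
        key = (feature_id, config.normalization, config.conservation,
               config.accessibility, config.n_gc_bins, config.retain_fraction)
        if key in self._norm:
            self.cache_stats["norm_hit"] += 1
            return self._norm[key]
        self.cache_stats["norm_miss"] += 1
        raw = (self.averaged_profile(feature_id) if config.conservation
               else self.raw_profile(feature_id))
        if config.normalization == "gc":
            norm = gc_rank_normalize(raw, self.gc, config.n_gc_bins)
        else:
            norm = rank_normalize(raw)
        if config.accessibility:
            norm = accessibility_filter(norm, self.access_profile(),
                                        config.retain_fraction)
        self._norm[key] = norm
        return norm

    def assignment(self, config: RunConfiguration) -> dict[str, np.ndarray]:
        mode, up, down = config.region_params()
        key = (mode, up, down, config.window_length, config.shift)
        if key in self._assignments:
            self.cache_stats["assign_hit"] += 1
            return self._assignments[key]
        self.cache_stats["assign_miss"] += 1
        regions = define_regions(self.genes, mode, self.genome.lengths,
                                 upstream=up, downstream=down)
        out = assign_windows(regions, self.windows)
        self._assignments[key] = out
        return out

    # ---- running configurations -----------------------------------------

    def validate(self, config: RunConfiguration) -> None:
        config.validate()
        if config.accessibility and self.accessibility is None:
            raise ValueError("configuration requests an accessibility filter "
                             "but no track was provided")
        if config.conservation and (self.phylo_weights is None
                                    or not self.species_profiles):
            raise ValueError("configuration requests conservation but no "
                             "multi-species profiles were provided")
        if not self.feature_ids:
            raise ValueError("no features (motifs or ChIP tracks) to score")

    def run(self, config: RunConfiguration,
            user_sets: dict[str, list[str]],
            universe: list[str] | None = None) -> list[EnrichmentResult]:
        """Run one configuration: one EnrichmentResult per (user set, feature).

        The universe defaults to every gene in the annotation.
        """
        self.validate(config)
        fp = config.fingerprint()
        if universe is None:
            universe = self.genes["gene_id"].to_list()
        assignment = self.assignment(config)
        results: list[EnrichmentResult] = []
        for feature_id in self.feature_ids:
            norm = self.normalized_profile(feature_id, config)
            scores = score_genes(norm, assignment)
            target = build_target_set(scores, universe, config.K,
                                      feature_id=feature_id, configuration=fp)
            for name, genes in user_sets.items():
                results.append(fisher_enrichment(target, genes, universe,
                                                 user_set_name=name))
        log.info("configuration %s: %d features x %d user sets -> %d tests",
                 fp, len(self.feature_ids), len(user_sets), len(results))
        return results


def run_configuration(pipeline: Pipeline, config: RunConfiguration,
                      user_sets: dict[str, list[str]],
                      universe: list[str] | None = None) -> pd.DataFrame:
    """Run one configuration and return the flattened result table."""
    return results_to_frame(pipeline.run(config, user_sets, universe))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(pipeline: Pipeline, configs: list[RunConfiguration],
            user_sets: dict[str, list[str]], out_dir: str,
            universe: list[str] | None = None,
            input_paths: dict[str, str] | None = None,
            max_p: float | None = None) -> dict:
    """Run every configuration, write reports and a machine-readable manifest.

    Invalid configurations are reported in the manifest; valid ones still
    run.  Window scores and other intermediates are shared across
    configurations through the pipeline caches.
    """
    if not configs:
        raise ValueError("at least one configuration is required")
    os.makedirs(out_dir, exist_ok=True)
    results_by_config: dict[str, list[EnrichmentResult]] = {}
    errors: list[dict] = []
    for config in configs:
        try:
            results_by_config[config.fingerprint()] = pipeline.run(
                config, user_sets, universe)
        except (ValueError, KeyError) as exc:
            log.error("configuration %s failed: %s", config.fingerprint(), exc)
            errors.append(dict(fingerprint=config.fingerprint(),
                               options=json.loads(config.canonical()),
                               error=str(exc)))
    display_p = max_p if max_p is not None else (
        configs[0].max_p if configs else 0.05)
    written = write_reports(results_by_config, out_dir, max_p=display_p) \
        if results_by_config else {}
    manifest = dict(
        version=__version__,
        seed=configs[0].seed,
        configurations=[
            dict(fingerprint=c.fingerprint(),
                 options=json.loads(c.canonical()))
            for c in configs],
        errors=errors,
        inputs={name: _sha256(path)
                for name, path in (input_paths or {}).items()},
        outputs=sorted(written),
        cache_stats=dict(pipeline.cache_stats),
    )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
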