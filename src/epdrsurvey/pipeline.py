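"""End-to-end family survey: search -> map -> filter -> classify -> conserve
-> tree -> report.

`run_survey` executes the full detection pipeline against one or more
proteomes; `classification_only_mode` runs the identical downstream stages on
a set already known to be family members (no E-value gate), which is the mode
used for re-analysing published family FASTA collections.  All randomness
(E-value calibration, bootstrap) derives from the single seed in
:class:`SurveyConfig`, so a rerun with the same config and inputs reproduces
the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .hmm import (EvalueCalibration, ProfileHMM, SeedAlignment, as_pairs,
                  build_profile, calibrate_evalue, hits_to_tsv, search,
                  score_sequence)
from .mapping import (ColumnMap, TrimSpec, alignment_from_colmaps,
                      deduplicate, filter_by_coverage, map_to_columns,
                      trim_alignment)
from .classify import (CanonicalColumns, DEFAULT_CANONICAL, ProfileCall,
                       call_profile, detect_signal_peptide, glyco_offsets,
                       length_stats, occupied_columns, scan_sequons)
from .conservation import column_profile, conserved_columns
from .phylogeny import (assign_clades, bootstrap_support, detect_expansions,
                        nj_tree, pairwise_distances)

__all__ = ["SurveyConfig", "SurveyReport", "StageError", "run_survey",
           "classification_only_mode", "summarize_by_group"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class SurveyConfig:
    """Thresholds and models for every pipeline stage (see docs/methods.md)."""

    evalue_cutoff: float = 1e-5
    dedup_threshold: float = 0.97
    coverage_threshold: float = 0.6
    trim_occupancy: float = 0.5
    conservation_min_freq: float = 0.9
    distance_model: str = "poisson"
    bootstrap_reps: int = 100
    expansion_threshold: int = 15
    expansion_clade_min: int = 2
    calibration_n_random: int = 1000
    match_occupancy: float = 0.5
    pseudocount: float = 1.0
    strict_calls: bool = False
    max_call_distance: int = 1
    signal_window: int = 8
    signal_hydropathy_min: float = 2.5
    seed: int = 0
    canonical: CanonicalColumns = field(default_factory=CanonicalColumns)

    def __post_init__(self):
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        for name in ("dedup_threshold", "coverage_threshold", "trim_occupancy",
                     "conservation_min_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canonical"] = dataclasses.asdict(self.canonical)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurveyConfig":
        d = dict(d)
        if "canonical" in d and isinstance(d["canonical"], Mapping):
            canon = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in d["canonical"].items()}
            d["canonical"] = CanonicalColumns(**canon)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SurveyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SurveyReport:
    """Per-sequence calls plus group summaries, tree and run metadata."""

    rows: pd.DataFrame
    species_counts: dict[str, int]
    conservation: dict
    conserved_cys_columns: dict[str, list[int]]
    tree: object | None
    clade_info: dict
    expansions: object | None
    lengths: dict
    metadata: dict
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        """Deterministic JSON payload (no timestamps, no heavy artifacts)."""
        return {
            "metadata": self.metadata,
            "n_sequences": int(len(self.rows)),
            "species_counts": dict(sorted(self.species_counts.items())),
            "conserved_cys_columns": self.conserved_cys_columns,
            "clade_info": {
                k: (sorted(v) if isinstance(v, frozenset) else v)
                for k, v in self.clade_info.items()
            },
            "expansions": (
                {
                    "counts": dict(sorted(self.expansions.counts.items())),
                    "expanded": self.expansions.expanded,
                    "clades": [
                        {"taxon": t, "size": s, "members": list(m)}
                        for t, s, m in self.expansions.clades
                    ],
                }
                if self.expansions is not None else None
            ),
            "lengths": self.lengths,
            "rows": self.rows.to_dict(orient="records"),
            "warnings": self.warnings,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)


def _stage(name):
    """Decorator-free stage guard: re-raise any error with the stage name."""
    class _Guard:
        def __init__(self, stage_name):
            self.name = stage_name

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(self.name, exc) from exc
            return False
    return _Guard(name)


def run_survey(
    proteomes,
    seed_alignment: SeedAlignment,
    config: SurveyConfig = SurveyConfig(),
    taxa: Mapping[str, str] | None = None,
    out_dir=None,
) -> SurveyReport:
    """Full survey of one or more proteomes against a seed alignment.

    ``proteomes`` accepts FASTA paths or ``(id, sequence)`` pairs; taxa are
    sniffed from ``id|taxon`` headers unless overridden by ``taxa``.
    Artifacts (accepted FASTA, calls TSV, conservation TSVs, Newick tree,
    report JSON) are written only when ``out_dir`` is given, and only after
    every stage has succeeded, so a failed run leaves no partial outputs.
    """
    from .io import read_proteomes, write_fasta

    warnings: list[str] = []
    with _stage("input"):
        pairs, taxon_of = read_proteomes(proteomes, taxa)
    with _stage("profile"):
        hmm = build_profile(seed_alignment, config.match_occupancy,
                            config.pseudocount)

    if not pairs:
        warnings.append("empty proteome: nothing to search")
        return _assemble_report(
            [], {}, {}, None, hmm, config, warnings,
            stage_counts={"input": 0}, out_dir=out_dir,
        )

    with _stage("calibration"):
        lens = np.array([len(s) for _, s in pairs], dtype=float)
        length_model = (float(np.median(lens)),
                        float(np.subtract(*np.percentile(lens, [75, 25])) / 2)
                        or 15.0)
        calibration = calibrate_evalue(
            hmm, n_random=config.calibration_n_random,
            length_model=length_model, seed=config.seed,
            database_size=len(pairs),
        )
    with _stage("search"):
        hits = search(hmm, pairs, calibration, cutoff=config.evalue_cutoff)
        accepted_hits = [h for h in hits if h.passed]
    with _stage("coverage-filter"):
        accepted_hits = filter_by_coverage(accepted_hits, hmm,
                                           config.coverage_threshold)
    seq_of = dict(pairs)
    accepted = [(h.sequence_id, seq_of[h.sequence_id]) for h in accepted_hits]
    hit_of = {h.sequence_id: h for h in accepted_hits}
    stage_counts = {
        "input": len(pairs),
        "passed_evalue": sum(1 for h in hits if h.passed),
        "passed_coverage": len(accepted),
    }
    report = _downstream(
        accepted, hit_of, hmm, seed_alignment, config, taxon_of, warnings,
        stage_counts, out_dir=out_dir, calibration=calibration,
    )
    return report


def classification_only_mode(
    sequences,
    seed_alignment: SeedAlignment,
    config: SurveyConfig = SurveyConfig(),
    taxa: Mapping[str, str] | None = None,
    out_dir=None,
) -> SurveyReport:
    """Run mapping/classification/conservation/tree on a known family set.

    Skips E-value search entirely (the inputs are presumed family members);
    downstream artifacts are identical in form to :func:`run_survey`.
    """
    from .io import read_proteomes

    warnings: list[str] = []
    with _stage("input"):
        pairs, taxon_of = read_proteomes(sequences, taxa)
    with _stage("profile"):
        hmm = build_profile(seed_alignment, config.match_occupancy,
                            config.pseudocount)
    with _stage("viterbi-mapping"):
        hit_of = {sid: score_sequence(hmm, (sid, seq)) for sid, seq in pairs}
    return _downstream(
        pairs, hit_of, hmm, seed_alignment, config, taxon_of, warnings,
        stage_counts={"input": len(pairs), "passed_evalue": None,
                      "passed_coverage": None},
        out_dir=out_dir, calibration=None,
    )


def _downstream(
    accepted, hit_of, hmm, seed_alignment, config, taxon_of, warnings,
    stage_counts, out_dir=None, calibration: EvalueCalibration | None = None,
) -> SurveyReport:
    """Shared pipeline tail from column mapping onward."""
    canon = config.canonical

    with _stage("column-mapping"):
        colmaps = {sid: map_to_columns(hit_of[sid], hmm)
                   for sid, _ in accepted}
    with _stage("dedup"):
        if accepted:
            accepted, cluster_report = deduplicate(
                accepted, colmaps, config.dedup_threshold
            )
            stage_counts["after_dedup"] = len(accepted)
        else:
            cluster_report = None

    with _stage("classification"):
        calls: dict[str, ProfileCall] = {}
        rows = []
        for sid, seq in accepted:
            cmap = colmaps[sid]
            vec = occupied_columns(seq, cmap, canon)
            call = call_profile(vec, strict=config.strict_calls,
                                max_distance=config.max_call_distance,
                                canon=canon, sequence_id=sid)
            pro_res = cmap.residue_at_column(canon.proline_column)
            proline = bool(pro_res is not None and seq[pro_res - 1] == "P")
            call = dataclasses.replace(call, proline_at_150=proline)
            calls[sid] = call
            sites = scan_sequons(seq)
            offsets, cys_mapped = glyco_offsets(sites, cmap, canon)
            if not cys_mapped:
                warnings.append(f"{sid}: second universal cysteine unmapped")
            signal = detect_signal_peptide(
                seq, window=config.signal_window,
                hydropathy_min=config.signal_hydropathy_min,
            )
            hit = hit_of[sid]
            rows.append({
                "id": sid,
                "taxon": taxon_of.get(sid, "unknown"),
                "length": len(seq),
                "bitscore": round(hit.bit_score, 4),
                "evalue": hit.e_value,
                "profile": call.assigned,
                "call_distance": call.distance,
                "occupied_columns": ",".join(map(str, call.occupied)),
                "proline_at_150": proline,
                "signal_peptide": signal.present,
                "n_sequons": len(sites),
                "glyco_offsets": ",".join(map(str, offsets)),
            })

    with _stage("conservation"):
        conservation = {}
        conserved_cys: dict[str, list[int]] = {}
        aligned = None
        if accepted:
            aligned = alignment_from_colmaps(accepted, colmaps,
                                             seed_alignment.n_columns)
            for profile in ("1", "2", "3"):
                group = [sid for sid, _ in accepted
                         if calls[sid].assigned == profile]
                if group:
                    prof = column_profile(aligned, group)
                    conservation[profile] = prof
                    conserved_cys[profile] = conserved_columns(
                        prof, "C", config.conservation_min_freq
                    )

    with _stage("phylogeny"):
        tree = None
        clade_info: dict = {}
        expansions = None
        if len(accepted) >= 3 and aligned is not None:
            trimmed, renumbering = trim_alignment(
                aligned, TrimSpec(config.trim_occupancy)
            )
            dist = pairwise_distances(trimmed, model=config.distance_model)
            tree = nj_tree(dist)
            tree = bootstrap_support(
                trimmed, reps=config.bootstrap_reps, seed=config.seed,
                model=config.distance_model, tree=tree,
            )
            profile_of = {sid: calls[sid].assigned for sid, _ in accepted}
            try:
                labels, clade_info = assign_clades(tree, profile_of)
            except ValueError as exc:
                labels = {sid: "unassigned" for sid, _ in accepted}
                clade_info = {"separating_edge": None, "misplaced": None,
                              "warning": str(exc)}
            if clade_info.get("warning"):
                warnings.append(f"clade assignment: {clade_info['warning']}")
            for row in rows:
                row["clade"] = labels.get(row["id"], "unassigned")
            edge = clade_info.get("separating_edge")
            if edge is not None:
                from .phylogeny import bipartitions

                node = bipartitions(tree).get(edge)
                clade_info["support"] = getattr(node, "support", None)
            accepted_taxa = {sid: taxon_of.get(sid, "unknown")
                             for sid, _ in accepted}
            expansions = detect_expansions(
                accepted_taxa, tree,
                count_threshold=config.expansion_threshold,
                clade_min=config.expansion_clade_min,
            )
        else:
            for row in rows:
                row["clade"] = "unassigned"
            if accepted:
                warnings.append("fewer than 3 sequences: tree skipped")
            # species counts still come from the accepted set below

    with _stage("report"):
        frame = pd.DataFrame(rows)
        if not frame.empty:
            frame = frame.sort_values("id").reset_index(drop=True)
        species_counts: dict[str, int] = {}
        for sid, _ in accepted:
            taxon = taxon_of.get(sid, "unknown")
            species_counts[taxon] = species_counts.get(taxon, 0) + 1
        lengths = (length_stats(accepted, calls) if accepted
                   else {"n": 0, "median": None, "q1": None, "q3": None})
        metadata = {
            "package_version": _pkg_version,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_counts": stage_counts,
            "calibration": (
                {"gumbel_lambda": calibration.gumbel_lambda,
                 "gumbel_mu": calibration.gumbel_mu,
                 "database_size": calibration.database_size}
                if calibration is not None else None
            ),
        }
        report = SurveyReport(
            rows=frame,
            species_counts=species_counts,
            conservation=conservation,
            conserved_cys_columns=conserved_cys,
            tree=tree,
            clade_info=clade_info,
            expansions=expansions,
            lengths=lengths,
            metadata=metadata,
            warnings=warnings,
        )

    if out_dir is not None:
        with _stage("artifacts"):
            _write_artifacts(report, accepted, hit_of, taxon_of, out_dir)
    return report


def _assemble_report(accepted, conservation, clade_info, tree, hmm, config,
                     warnings, stage_counts, out_dir=None) -> SurveyReport:
    """Empty-input report (success with warning, per the survey contract)."""
    report = SurveyReport(
        rows=pd.DataFrame(columns=["id", "taxon", "length", "bitscore",
                                   "evalue", "profile", "clade"]),
        species_counts={},
        conservation=conservation,
        conserved_cys_columns={},
        tree=tree,
        clade_info=clade_info,
        expansions=None,
        lengths={"n": 0, "median": None, "q1": None, "q3": None},
        metadata={
            "package_version": _pkg_version,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_counts": stage_counts,
            "calibration": None,
        },
        warnings=warnings,
    )
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        report.write_json(Path(out_dir) / "report.json")
    return report


def _write_artifacts(report: SurveyReport, accepted, hit_of, taxon_of,
                     out_dir) -> None:
    from .io import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(accepted, out / "accepted.fasta",
                taxa={sid: taxon_of.get(sid, "unknown") for sid, _ in accepted})
    report.rows.to_csv(out / "calls.tsv", sep="\t", index=False)
    for profile, prof in report.conservation.items():
        prof.to_frame().to_csv(out / f"conservation_profile{profile}.tsv",
                               sep="\t", index=False)
    if report.tree is not None:
        report.tree.write(str(out / "tree.nwk"))
    hits = sorted(hit_of.values(), key=lambda h: h.sequence_id)
    if hits and hits[0].e_value is not None:
        hits_to_tsv(hits, out / "hits.tsv")
    report.write_json(out / "report.json")


def summarize_by_group(report: SurveyReport) -> dict[str, pd.DataFrame]:
    """Per-species, per-profile and profile x clade summary tables."""
    rows = report.rows
    if rows.empty:
        empty = pd.DataFrame()
        return {"per_species": empty, "per_profile": empty,
                "profile_by_clade": empty, "presence": empty}
    per_species = (rows.groupby("taxon").size().rename("n_sequences")
                   .reset_index().sort_values("taxon").reset_index(drop=True))
    per_profile = (rows.groupby("profile").size().rename("n_sequences")
                   .reset_index().sort_values("profile").reset_index(drop=True))
    crosstab = pd.crosstab(rows["profile"], rows["clade"])
    presence = (pd.crosstab(rows["taxon"], rows["profile"]) > 0).astype(int)
    return {
        "per_species": per_species,
        "per_profile": per_profile,
        "profile_by_clade": crosstab,
        "presence": presence,
    }
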