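"""End-to-end orchestration: ingest → dedup → match → extract → screen → subgroups.

Every analysis stage is deterministic; the only randomness in the package
lives in :mod:`faerspv.synthetic`. The run manifest records row counts and
exclusion tallies at every stage and asserts stage-count conservation
(reports in = reports retained + exclusions).
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from . import cohort, disproportionality, faers_io, subgroups

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: Path
    out_dir: Path
    drug_dictionary: Optional[Path] = None
    meddra: Optional[Path] = None
    min_a: int = 3
    yates: bool = True
    bcpnn: disproportionality.BcpnnParams = field(
        default_factory=disproportionality.BcpnnParams
    )
    age_threshold: float = 70.5
    elderly_threshold: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        bcpnn = disproportionality.BcpnnParams(**raw.pop("bcpnn", {}))
        for key in ("input_dir", "out_dir", "drug_dictionary", "meddra"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(bcpnn=bcpnn, **raw)


@dataclass
class PipelineResult:
    bundles: List[faers_io.CaseBundle]
    matched: List[Tuple[faers_io.CaseBundle, str, List[int]]]
    cae_cases: List[cohort.CAECase]
    screen_df: pd.DataFrame
    lowcount_df: pd.DataFrame
    soc_dist: pd.DataFrame
    demographics: subgroups.DemographicSummary
    onset: subgroups.OnsetExtraction
    onset_dist: subgroups.OnsetDistribution
    death_stats: Dict[str, subgroups.DeathGroupStats]
    co_reported: subgroups.CoReportedResult
    rollup: subgroups.ClassRollup
    manifest: Dict[str, object]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_from_rows(
    rows_by_kind: Dict[str, List[faers_io.RawTableRow]],
    dictionary: Optional[List[cohort.DrugDictionaryEntry]] = None,
    meddra: Optional[cohort.MeddraMap] = None,
    min_a: int = 3,
    yates: bool = True,
    bcpnn_params: Optional[disproportionality.BcpnnParams] = None,
    age_threshold: float = 70.5,
) -> PipelineResult:
    dictionary = dictionary or cohort.load_drug_dictionary()
    meddra = meddra or cohort.load_meddra()

    demo_raw = rows_by_kind.get("DEMO", [])
    demo = faers_io.deduplicate(demo_raw)
    linked = faers_io.link_cases({**rows_by_kind, "DEMO": demo})
    bundles = linked.bundles

    matched: List[Tuple[faers_io.CaseBundle, str, List[int]]] = []
    n_unmatched = n_ambiguous = 0
    for b in bundles:
        m = cohort.match_case(b, dictionary)
        if m.ambiguous:
            n_ambiguous += 1
        elif m.product_id is None:
            n_unmatched += 1
        else:
            matched.append((b, m.product_id, m.matched_drug_seqs))

    in_window: List[Tuple[faers_io.CaseBundle, str, List[int]]] = []
    n_out_window = n_missing_quarter = 0
    for b, pid, seqs in matched:
        entry = cohort.entry_for(pid, dictionary)
        if b.demographics.event_quarter is None:
            n_missing_quarter += 1
        elif cohort.in_search_window(b, entry):
            in_window.append((b, pid, seqs))
        else:
            n_out_window += 1

    product_of = {b.primaryid: pid for b, pid, _ in in_window}
    reports = disproportionality.ReportSet.from_bundles(
        (b, product_of.get(b.primaryid)) for b in bundles
    )

    extraction = cohort.extract_cae(in_window, meddra)
    cae_cases = extraction.cases

    cae_pts = sorted({pt for c in cae_cases for pt in c.cae_pts})
    products = sorted({c.product_id for c in cae_cases})
    screen_df, lowcount_df = disproportionality.screen(
        reports, products, cae_pts, min_a=min_a, yates=yates, bcpnn_params=bcpnn_params
    )

    soc_dist = cohort.soc_distribution(((b, pid) for b, pid, _ in in_window), meddra)
    demo_summary = subgroups.demographic_summary(cae_cases)
    onset = subgroups.make_onset_records(cae_cases)
    onset_dist = subgroups.onset_distribution(onset.records)
    death_stats, _ = subgroups.death_subset(cae_cases)
    co_rep = subgroups.co_reported(cae_cases, meddra)
    rollup = subgroups.component_class_rollup(
        subgroups.cae_pt_counts(cae_cases), dictionary
    )

    manifest: Dict[str, object] = {
        "software_version": __version__,
        "config": {"min_a": min_a, "yates": yates, "age_threshold": age_threshold},
        "stages": {
            "demo_rows_in": len(demo_raw),
            "demo_after_dedup": len(demo),
            "dedup_removed": len(demo_raw) - len(demo),
            "orphan_rows": linked.orphan_counts,
            "bundles": len(bundles),
            "matched": len(matched),
            "unmatched": n_unmatched,
            "ambiguous": n_ambiguous,
            "in_window": len(in_window),
            "out_of_window": n_out_window,
            "missing_quarter": n_missing_quarter,
            "cae_cases": len(cae_cases),
            "non_cae_matched": extraction.n_without_cae,
            "cae_pt_total": sum(len(c.cae_pts) for c in cae_cases),
            "unmapped_pt_reports": sum(extraction.unmapped_tally.values()),
            "onset_included_cases": onset.n_cases_in,
            "onset_excluded_partial_dates": onset.excluded_partial_dates,
            "onset_excluded_negative": onset.excluded_negative,
        },
    }
    s = manifest["stages"]
    conservation = {
        "match": s["bundles"] == s["matched"] + s["unmatched"] + s["ambiguous"],
        "window": s["matched"]
        == s["in_window"] + s["out_of_window"] + s["missing_quarter"],
        "cae": s["in_window"] == s["cae_cases"] + s["non_cae_matched"],
        "onset": s["cae_cases"]
        == s["onset_included_cases"]
        + s["onset_excluded_partial_dates"]
        + s["onset_excluded_negative"],
    }
    manifest["conservation"] = conservation
    if not all(conservation.values()):
        raise StageError(
            "manifest", AssertionError(f"stage-count conservation violated: {conservation}")
        )

    return PipelineResult(
        bundles=bundles,
        matched=in_window,
        cae_cases=cae_cases,
        screen_df=screen_df,
        lowcount_df=lowcount_df,
        soc_dist=soc_dist,
        demographics=demo_summary,
        onset=onset,
        onset_dist=onset_dist,
        death_stats=death_stats,
        co_reported=co_rep,
        rollup=rollup,
        manifest=manifest,
    )


def run_from_frames(tables: Dict[str, pd.DataFrame], **kwargs) -> PipelineResult:
    """Run on in-memory string-typed tables (e.g. straight from the generator)."""
    rows = {
        kind: faers_io.rows_from_frame(df, kind)
        for kind, df in tables.items()
        if kind in faers_io.TABLE_KINDS
    }
    return run_from_rows(rows, **kwargs)


def _death_frame(stats: Dict[str, subgroups.DeathGroupStats]) -> pd.DataFrame:
    rows = []
    for pid in sorted(stats):
        gs = stats[pid]
        top = "; ".join(f"{r.pt} ({r.n})" for r in gs.pt_counts.head(5).itertuples())
        rows.append(
            {
                "group": pid,
                "n_death_cases": gs.n_cases,
                "age_mean": gs.age_mean,
                "age_median": gs.age_median,
                "age_missing_frac": gs.age_missing_frac,
                "top_pts": top,
            }
        )
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.demographics.to_frame().to_csv(out_dir / "demographic_summary.csv", index=False)
    result.screen_df.to_csv(out_dir / "signal_screen.csv", index=False)
    result.lowcount_df.to_csv(out_dir / "bcpnn_lowcount.csv", index=False)
    result.soc_dist.to_csv(out_dir / "soc_distribution.csv", index=False)
    with open(out_dir / "heatmap_prr.json", "w") as fh:
        json.dump(disproportionality.heatmap_matrix(result.screen_df, "prr"), fh, indent=1)
    with open(out_dir / "intensity_matrix.json", "w") as fh:
        json.dump(disproportionality.intensity_matrix(result.screen_df), fh, indent=1)
    onset_df = pd.DataFrame(
        {
            "bin": result.onset_dist.bin_counts.index,
            "n_cases": result.onset_dist.bin_counts.to_numpy(),
        }
    )
    onset_df.to_csv(out_dir / "onset.csv", index=False)
    with open(out_dir / "onset_cumulative.json", "w") as fh:
        json.dump(
            {
                "days": [int(d) for d in result.onset_dist.cumulative["days"]],
                "cum_prop": [float(p) for p in result.onset_dist.cumulative["cum_prop"]],
            },
            fh,
        )
    _death_frame(result.death_stats).to_csv(out_dir / "death_subset.csv", index=False)
    co = pd.concat(
        [
            result.co_reported.soc_counts.assign(level="SOC").rename(columns={"soc": "term"}),
            result.co_reported.pt_counts.assign(level="PT").rename(columns={"pt": "term"}),
        ],
        ignore_index=True,
    )
    co.to_csv(out_dir / "co_reported.csv", index=False)
    manifest = dict(result.manifest)
    manifest["co_reported_share_pct"] = result.co_reported.share_pct
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """File-to-file run; removes partial outputs and re-raises on stage failure."""
    stage = "ingest"
    try:
        rows = faers_io.read_tables(config.input_dir)
        if not rows.get("DEMO"):
            logger.warning("no DEMO rows found under %s: writing empty report", config.input_dir)
        dictionary = cohort.load_drug_dictionary(config.drug_dictionary)
        meddra = cohort.load_meddra(config.meddra)
        stage = "analyze"
        result = run_from_rows(
            rows,
            dictionary=dictionary,
            meddra=meddra,
            min_a=config.min_a,
            yates=config.yates,
            bcpnn_params=config.bcpnn,
            age_threshold=config.age_threshold,
        )
        stage = "write"
        write_outputs(result, config.out_dir)
    except Exception as exc:
        if isinstance(exc, StageError):
            stage = exc.stage
        out = Path(config.out_dir)
        if stage == "write" and out.exists():
            shutil.rmtree(out, ignore_errors=True)
        raise StageError(stage, exc) from exc
    for name, count in result.manifest["stages"].items():
        logger.info("stage %-28s %s", name, count)
    return result.manifest
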