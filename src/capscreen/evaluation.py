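"""Threshold-sweep evaluation and confirmation statistics.

The DS threshold for affected samples and for the control pool are swept over
a grid; each cell reruns the cascade and counts candidates before and after
the homology check, the confirmed candidates among them, and the resulting
false-positive and false-negative rates. FPR is the fraction of surviving
candidates that were not confirmed; FNR measures confirmed variants lost
relative to the most permissive evaluated setting. Confirmation labels come
from Sanger results or from the synthetic truth set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from ._util import round_half_up
from .filter_cascade import Candidate, CascadeResult, CascadeThresholds, FilterTrace
from .io_formats import VariantKey


@dataclass(frozen=True)
class SweepCell:
    ds_individuals: float
    ds_control: float
    candidates_before_homology: int
    candidates_after_homology: int
    confirmed: int
    fpr: int  # printed-style integer percent
    fnr: int

    def __post_init__(self) -> None:
        if self.confirmed > self.candidates_after_homology:
            raise ValueError("confirmed count exceeds surviving candidates")
        if not (0 <= self.fpr <= 100 and 0 <= self.fnr <= 100):
            raise ValueError("rates must be percentages")


@dataclass(frozen=True)
class ConfirmationStats:
    n_candidates: int
    n_confirmed: int
    confirmation_rate: float  # proportion, 2 decimals
    mean_ds_confirmed: float
    ds_range_confirmed: tuple[float, float]
    mean_ds_ruled_out: float
    ds_range_ruled_out: tuple[float, float]


def fpr_percent(candidates_after_homology: int, confirmed: int) -> int:
    """False positives among surviving candidates, as an integer percent."""
    if candidates_after_homology == 0:
        return 0
    return int(
        round_half_up(
            100.0 * (candidates_after_homology - confirmed) / candidates_after_homology
        )
    )


def fnr_percent(confirmed: int, max_confirmed: int) -> int:
    """Confirmed variants lost versus the most permissive setting, as percent."""
    if max_confirmed == 0:
        return 0
    return int(round_half_up(100.0 * (max_confirmed - confirmed) / max_confirmed))


def sweep_thresholds(
    run_family,  # Callable[[CascadeThresholds], CascadeResult]
    ds_individual_grid: Sequence[float],
    ds_control_grid: Sequence[float],
    confirmed_keys: set[VariantKey],
    base_thresholds: CascadeThresholds = CascadeThresholds(),
) -> list[SweepCell]:
    """Evaluate the cascade over a DS-threshold grid for one family.

    ``run_family`` executes the cascade at given thresholds; the FNR
    denominator is the confirmed count at the most permissive grid point
    (lowest thresholds), evaluated first.
    """
    if not ds_individual_grid or not ds_control_grid:
        raise ValueError("threshold grids must be non-empty")
    from dataclasses import replace

    results: dict[tuple[float, float], CascadeResult] = {}
    for ds_ind in ds_individual_grid:
        for ds_ctrl in ds_control_grid:
            th = replace(base_thresholds, min_ds=ds_ind, control_min_ds=ds_ctrl)
            results[(ds_ind, ds_ctrl)] = run_family(th)

    most_permissive = (min(ds_individual_grid), min(ds_control_grid))
    max_confirmed = sum(
        1 for c in results[most_permissive].candidates if c.key in confirmed_keys
    )
    cells = []
    for ds_ind in ds_individual_grid:
        for ds_ctrl in ds_control_grid:
            res = results[(ds_ind, ds_ctrl)]
            confirmed = sum(1 for c in res.candidates if c.key in confirmed_keys)
            cells.append(
                SweepCell(
                    ds_individuals=ds_ind,
                    ds_control=ds_ctrl,
                    candidates_before_homology=res.trace.pre_homology_variants,
                    candidates_after_homology=len(res.candidates),
                    confirmed=confirmed,
                    fpr=fpr_percent(len(res.candidates), confirmed),
                    fnr=fnr_percent(confirmed, max_confirmed),
                )
            )
    return cells


def confirmation_stats(
    candidate_member_ds: Mapping[VariantKey, Sequence[float]],
    confirmed: set[VariantKey],
) -> ConfirmationStats:
    """Confirmation rate and group DS summaries.

    Mean DS is pooled over every per-member DS value within a group (a
    two-member family contributes two values per candidate); the rate is
    rounded half-up to 2 decimals.
    """
    n = len(candidate_member_ds)
    if n == 0:
        raise ValueError("confirmation rate undefined with zero candidates")
    conf_vals = [v for k, vs in candidate_member_ds.items() if k in confirmed for v in vs]
    out_vals = [v for k, vs in candidate_member_ds.items() if k not in confirmed for v in vs]
    n_conf = sum(1 for k in candidate_member_ds if k in confirmed)

    def summarize(vals: Sequence[float]) -> tuple[float, tuple[float, float]]:
        if not vals:
            return 0.0, (0.0, 0.0)
        return sum(vals) / len(vals), (min(vals), max(vals))

    mean_c, range_c = summarize(conf_vals)
    mean_o, range_o = summarize(out_vals)
    return ConfirmationStats(
        n_candidates=n,
        n_confirmed=n_conf,
        confirmation_rate=round_half_up(n_conf / n, 2),
        mean_ds_confirmed=mean_c,
        ds_range_confirmed=range_c,
        mean_ds_ruled_out=mean_o,
        ds_range_ruled_out=range_o,
    )


# ---------------------------------------------------------------------------
# report rendering


def _tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    lines = ["\t".join(header)]
    lines.extend("\t".join(str(x) for x in row) for row in rows)
    path.write_text("\n".join(lines) + "\n")


def render_reports(
    out_dir: str | Path,
    summaries: Mapping[str, object] | None = None,
    qc_rows: Sequence[Sequence] | None = None,
    sweep: Sequence[SweepCell] | None = None,
    traces: Mapping[str, FilterTrace] | None = None,
    candidates: Mapping[str, Sequence[Candidate]] | None = None,
) -> dict[str, Path]:
    """Write the TSV report bundle. Same inputs give byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if summaries is not None:
        rows = [
            (
                s, m.total_reads, m.aligned_reads, m.pct_aligned, m.on_target_reads,
                m.pct_on_target, m.coverage_pct, m.mean_depth, m.median_depth,
            )
            for s, m in sorted(summaries.items())
        ]
        paths["summary"] = out / "summary.tsv"
        _tsv(
            paths["summary"],
            ["sample", "total_reads", "aligned", "pct_aligned", "on_target",
             "pct_on_target", "coverage_pct", "mean_depth", "median_depth"],
            rows,
        )
    if qc_rows is not None:
        paths["covqc"] = out / "coverage_qc.tsv"
        _tsv(paths["covqc"], ["sample", "mean_is", "sd_is", "upper", "lower",
                              "n_flagged", "n_flagged_at_edges"], qc_rows)
    if sweep is not None:
        paths["sweep"] = out / "sweep.tsv"
        _tsv(
            paths["sweep"],
            ["ds_individuals", "ds_control", "before_homology", "after_homology",
             "confirmed", "fpr", "fnr"],
            [(c.ds_individuals, c.ds_control, c.candidates_before_homology,
              c.candidates_after_homology, c.confirmed, c.fpr, c.fnr) for c in sweep],
        )
    if traces is not None:
        rows = []
        for fam, t in sorted(traces.items()):
            for i, member in enumerate(sorted(t.initial_snps)):
                rows.append(
                    (
                        fam, member, t.initial_snps[member], t.after_control[member],
                        t.shared_by_family if i == 0 else "",
                        t.undescribed if i == 0 else "",
                        t.consequences if i == 0 else "",
                        t.exonic if i == 0 else "",
                        t.candidates if i == 0 else "",
                    )
                )
        paths["trace"] = out / "filter_trace.tsv"
        _tsv(paths["trace"], ["family", "individual", "snps", "after_control",
                              "shared_by_family", "undescribed", "consequences",
                              "exonic", "candidates"], rows)
    if candidates is not None:
        rows = []
        for fam, cands in sorted(candidates.items()):
            for c in cands:
                chrom, pos, ref, alt = c.key
                members = sorted(c.member_calls)
                ds = "/".join(str(c.member_calls[m].printed_ds) for m in members)
                qs = "/".join(str(c.member_calls[m].printed_qs) for m in members)
                klasses = ",".join(sorted({q.klass for q in c.consequences}))
                rows.append((fam, chrom, pos, ref, alt, qs, ds, klasses))
        paths["candidates"] = out / "candidates.tsv"
        _tsv(paths["candidates"],
             ["family", "chrom", "pos", "ref", "alt", "qs", "ds", "consequence"],
             rows)
    return paths
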