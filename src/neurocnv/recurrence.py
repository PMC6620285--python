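"""Cross-sample recurrence ("penetrance") analysis of CNV calls.

The genome is partitioned at every call breakpoint into atomic
fragments, so each call is an exact union of consecutive fragments.  Per
fragment, direction and sample group, the carrier frequency is the
percentage of group samples whose same-direction call covers the
fragment.  Recurrent regions are fragments reaching the recurrence
threshold (default 10%, inclusive) in the chosen scope, merged back into
maximal regions where adjacent fragments share identical carrier sets;
gains and losses are always separate events.  Case-exclusive filtering
drops regions overlapped by any same-direction control call.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .simulate import chrom_sort_key

__all__ = [
    "round_half_up",
    "fragment_breakpoints",
    "compute_penetrance",
    "select_recurrent",
    "filter_case_exclusive",
    "recurrent_regions",
    "write_recurrent_tsv",
    "write_recurrent_bed",
]

RECURRENCE_MIN_PCT = 10.0
SCOPES = ("cases", "group1", "group2")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero upward, as printed frequencies are."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def fragment_breakpoints(calls: pd.DataFrame) -> pd.DataFrame:
    """Partition each chromosome's covered span into atomic fragments.

    Breakpoints are the union of all call starts/ends on a chromosome
    (both directions), so every call is an exact union of consecutive
    fragments.  One output row per (fragment, direction) with a
    non-empty carrier set.

    Returns a DataFrame with columns chrom, start, end, direction,
    carriers (sorted tuple of sample ids).
    """
    if calls.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction", "carriers"])
    rows = []
    for chrom, sub in calls.groupby("chrom", sort=False):
        cuts = np.unique(np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()]))
        frag_start = cuts[:-1]
        frag_end = cuts[1:]
        for direction in ("gain", "loss"):
            d = sub[sub["direction"] == direction]
            if d.empty:
                continue
            cover: dict[int, set] = {}
            for s0, e0, sample in zip(d["start"], d["end"], d["sample_id"]):
                # call endpoints are breakpoints, so coverage is exact
                i0 = np.searchsorted(frag_start, s0)
                i1 = np.searchsorted(frag_end, e0, side="left")
                for k in range(i0, i1 + 1):
                    if frag_start[k] >= s0 and frag_end[k] <= e0:
                        cover.setdefault(k, set()).add(sample)
            for k in sorted(cover):
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(frag_start[k]),
                        "end": int(frag_end[k]),
                        "direction": direction,
                        "carriers": tuple(sorted(cover[k])),
                    }
                )
    out = pd.DataFrame(rows)
    out["_ck"] = out["chrom"].map(chrom_sort_key)
    out = out.sort_values(["_ck", "start", "direction"], kind="mergesort").drop(columns="_ck")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Penetrance
# ---------------------------------------------------------------------------

def _group_sets(metadata: pd.DataFrame) -> dict[str, set]:
    sets = {
        g: set(metadata.loc[metadata["group"] == g, "sample_id"])
        for g in ("control", "group1", "group2")
    }
    sets["cases"] = sets["group1"] | sets["group2"]
    return sets


def compute_penetrance(fragments: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Carrier percentage per fragment, direction and sample group.

    ``frequency_pct = 100 x carriers / group size``, rounded half-up to
    two decimals (the precision recurrence tables are printed at).
    """
    sets = _group_sets(metadata)
    known = set(metadata["sample_id"])
    rows = []
    for rec in fragments.itertuples(index=False):
        carriers = set(rec.carriers)
        unknown = carriers - known
        if unknown:
            raise ValueError(f"carrier ids not in metadata: {sorted(unknown)}")
        row = {
            "chrom": rec.chrom,
            "start": rec.start,
            "end": rec.end,
            "direction": rec.direction,
            "carriers": rec.carriers,
        }
        for g in ("control", "group1", "group2", "cases"):
            members = carriers & sets[g]
            size = len(sets[g])
            row[f"carriers_{g}"] = tuple(sorted(members))
            row[f"n_{g}"] = len(members)
            row[f"freq_{g}"] = round_half_up(100.0 * len(members) / size) if size else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recurrent-region selection
# ---------------------------------------------------------------------------

def select_recurrent(
    penetrance: pd.DataFrame,
    min_pct: float = RECURRENCE_MIN_PCT,
    scope: str = "cases",
) -> pd.DataFrame:
    """Keep fragments recurrent in ``scope`` and merge them into maximal regions.

    A fragment is recurrent when its scope frequency is at least
    ``min_pct`` (inclusive).  Adjacent selected fragments with the same
    direction and identical full carrier sets are merged back into one
    region.  Gains and losses are evaluated independently and never
    merged together.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    if penetrance.empty:
        return _empty_regions()
    kept = penetrance[penetrance[f"freq_{scope}"] >= min_pct]
    if kept.empty:
        return _empty_regions()

    kept = kept.assign(_ck=kept["chrom"].map(chrom_sort_key)).sort_values(
        ["_ck", "direction", "start"], kind="mergesort"
    )
    regions = []
    cur = None
    for rec in kept.itertuples(index=False):
        if (
            cur is not None
            and rec.chrom == cur["chrom"]
            and rec.direction == cur["direction"]
            and rec.start == cur["end"]
            and rec.carriers == cur["carriers"]
        ):
            cur["end"] = rec.end
            continue
        if cur is not None:
            regions.append(cur)
        cur = {
            "chrom": rec.chrom,
            "start": rec.start,
            "end": rec.end,
            "direction": rec.direction,
            "scope": scope,
            "frequency_pct": getattr(rec, f"freq_{scope}"),
            "carriers": getattr(rec, f"carriers_{scope}"),
            "n_carriers": getattr(rec, f"n_{scope}"),
            "n_control_carriers": rec.n_control,
            # full carrier set drives the merge rule
            "_all_carriers": rec.carriers,
        }
    if cur is not None:
        regions.append(cur)

    out = pd.DataFrame(regions).rename(columns={"_all_carriers": "all_carriers"})
    out["_ck"] = out["chrom"].map(chrom_sort_key)
    out = out.sort_values(["_ck", "start", "direction"], kind="mergesort").drop(columns="_ck")
    return out.reset_index(drop=True)


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chrom", "start", "end", "direction", "scope", "frequency_pct",
            "carriers", "n_carriers", "n_control_carriers", "all_carriers",
        ]
    )


def filter_case_exclusive(
    recurrent: pd.DataFrame,
    control_calls: pd.DataFrame,
    direction_matched: bool = True,
) -> pd.DataFrame:
    """Drop recurrent regions seen in any individual control.

    A region is dropped when any control call of the same direction
    (any direction if ``direction_matched`` is False) overlaps it by at
    least 1 bp; survivors are flagged ``case_exclusive``.
    """
    if recurrent.empty:
        out = recurrent.copy()
        out["case_exclusive"] = pd.Series(dtype=bool)
        return out
    keep = []
    for rec in recurrent.itertuples(index=False):
        cc = control_calls
        if not cc.empty:
            mask = (
                (cc["chrom"] == rec.chrom)
                & (cc["end"] > rec.start)
                & (cc["start"] < rec.end)
            )
            if direction_matched:
                mask &= cc["direction"] == rec.direction
            hit = bool(mask.any())
        else:
            hit = False
        keep.append(not hit)
    out = recurrent[np.array(keep, dtype=bool)].copy()
    out["case_exclusive"] = True
    return out.reset_index(drop=True)


def recurrent_regions(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    min_pct: float = RECURRENCE_MIN_PCT,
    scope: str = "cases",
    case_exclusive: bool = True,
    direction_matched: bool = True,
) -> pd.DataFrame:
    """Full recurrence chain: fragment -> penetrance -> select -> control filter.

    Penetrance is computed on case calls only (case carrier frequencies);
    the control filter then uses the individual control calls directly.
    """
    sets = _group_sets(metadata)
    case_calls = calls[calls["sample_id"].isin(sets["cases"])]
    control_calls = calls[calls["sample_id"].isin(sets["control"])]
    fragments = fragment_breakpoints(case_calls)
    if fragments.empty:
        out = _empty_regions()
        out["case_exclusive"] = pd.Series(dtype=bool)
        return out
    pen = compute_penetrance(fragments, metadata)
    regions = select_recurrent(pen, min_pct=min_pct, scope=scope)
    if case_exclusive:
        regions = filter_case_exclusive(regions, control_calls, direction_matched)
    else:
        regions = regions.copy()
        regions["case_exclusive"] = False
    return regions


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_recurrent_tsv(regions: pd.DataFrame, path) -> None:
    """Recurrence table in the printed dialect: 1-based inclusive coordinates."""
    out = pd.DataFrame(
        {
            "Chr": regions["chrom"],
            "Start": regions["start"] + 1,
            "Stop": regions["end"],
            "Aberration Size (bps)": regions["end"] - regions["start"],
            "Aberration": regions["direction"],
            "Scope": regions["scope"],
            "Frequency (%)": regions["frequency_pct"],
            "Genes": [
                ";".join(g) if isinstance(g, (list, tuple)) else ""
                for g in regions.get("genes", [()] * len(regions))
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_recurrent_bed(regions: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"],
            "end": regions["end"],
            "name": regions["direction"] + "_" + regions["scope"],
            "score": regions["frequency_pct"],
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
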