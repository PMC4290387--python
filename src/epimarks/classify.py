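"""Two-step cross-species classification of enriched regions.

Peak-caller outputs disagree across individuals mostly at the calling
threshold, which inflates apparent between-species differences.  The
classifier counteracts this with two cutoffs: a stringent one identifies
high-confidence enriched regions per individual, and a relaxed one is then
applied only at positions overlapping (or orthologous to) a stringent region
from any other individual, borrowing strength across individuals and species.

Confidence semantics differ by mark: narrow-peak marks carry an FDR in
[0, 1] (smaller is better); the broad repressive mark carries a domain score
>= 0 (larger is better).  All threshold comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from epimarks.constants import MARKS, BROAD_MARKS


@dataclass
class CutoffPolicy:
    """Stringent and relaxed thresholds per mark.

    For narrow marks the values are FDR cutoffs (pass if FDR <= cutoff); for
    the broad mark the stringent value is a minimum domain score (pass if
    score >= cutoff) and the relaxed rule is mere presence of a domain call.
    """

    stringent_fdr: dict = field(
        default_factory=lambda: {
            "H3K4me1": 0.05,
            "H3K4me3": 0.05,
            "H3K27ac": 0.05,
            "PolII": 0.05,
        }
    )
    relaxed_fdr: dict = field(
        default_factory=lambda: {
            "H3K4me1": 0.15,
            "H3K4me3": 0.10,
            "H3K27ac": 0.15,
            "PolII": 0.10,
        }
    )
    stringent_score: float = 20.0

    def __post_init__(self) -> None:
        for mark, relaxed in self.relaxed_fdr.items():
            if relaxed < self.stringent_fdr[mark]:
                raise ValueError(
                    f"relaxed cutoff for {mark} is stricter than the stringent one"
                )

    def passes_stringent(self, mark: str, confidence: np.ndarray) -> np.ndarray:
        if mark in BROAD_MARKS:
            return np.asarray(confidence) >= self.stringent_score
        return np.asarray(confidence) <= self.stringent_fdr[mark]

    def passes_relaxed(self, mark: str, confidence: np.ndarray) -> np.ndarray:
        if mark in BROAD_MARKS:
            # any domain call qualifies at the relaxed step
            return np.ones(np.shape(confidence), dtype=bool)
        return np.asarray(confidence) <= self.relaxed_fdr[mark]


def _validate_confidence(calls: pd.DataFrame) -> None:
    for mark, df in calls.groupby("mark"):
        conf = df["confidence"].to_numpy(dtype=float)
        if mark in BROAD_MARKS:
            if (conf < 0).any():
                raise ValueError(f"negative domain score for mark {mark}")
        else:
            if ((conf < 0) | (conf > 1)).any():
                raise ValueError(f"FDR outside [0, 1] for mark {mark}")


def _interval_trees(df: pd.DataFrame) -> dict:
    trees: dict = {}
    for chrom, sub in df.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            if e > s:
                tree.addi(int(s), int(e))
        trees[chrom] = tree
    return trees


def filter_mappable_regions(
    calls: pd.DataFrame,
    mappable_windows: pd.DataFrame,
    ortholog_map: pd.DataFrame | None = None,
    min_aligned_fraction: float = 0.2,
) -> pd.DataFrame:
    """Apply the mappability and orthology screens to raw calls.

    A call is retained if it overlaps at least one retained 200-bp mappable
    window, and (when an ortholog map is supplied) its cross-genome mapping
    aligns at least ``min_aligned_fraction`` of its bases (boundary
    inclusive).  A call with no ortholog-map entry failed to map and is
    dropped.
    """
    known = set(mappable_windows["chrom"].unique())
    bad = set(calls["chrom"].unique()) - known
    if bad:
        raise ValueError(f"unknown chromosome(s) in calls: {sorted(bad)}")

    trees = _interval_trees(mappable_windows)
    keep_map = np.array(
        [
            bool(trees[c].overlap(int(s), int(e)))
            for c, s, e in zip(calls["chrom"], calls["start"], calls["end"])
        ]
    )
    kept = calls.loc[keep_map]

    if ortholog_map is None:
        return kept.reset_index(drop=True)

    # best aligned fraction among ortholog-map regions overlapping each call,
    # considering entries anchored in the call's own species on either side
    frac_trees: dict = {}
    for side in ("a", "b"):
        cols = {
            "species": f"species_{side}",
            "chrom": f"chrom_{side}",
            "start": f"start_{side}",
            "end": f"end_{side}",
        }
        for (sp, chrom), sub in ortholog_map.groupby([cols["species"], cols["chrom"]]):
            tree = frac_trees.setdefault((sp, chrom), IntervalTree())
            for s, e, f in zip(sub[cols["start"]], sub[cols["end"]], sub["aligned_fraction"]):
                if e > s:
                    tree.addi(int(s), int(e), float(f))

    keep_orth = []
    for sp, c, s, e in zip(kept["species"], kept["chrom"], kept["start"], kept["end"]):
        tree = frac_trees.get((sp, c))
        hits = tree.overlap(int(s), int(e)) if tree is not None else set()
        best = max((iv.data for iv in hits), default=0.0)
        keep_orth.append(best >= min_aligned_fraction)
    return kept.loc[keep_orth].reset_index(drop=True)


def two_step_classify(
    calls: pd.DataFrame,
    ortholog_map: pd.DataFrame | None = None,
    policy: CutoffPolicy | None = None,
) -> pd.DataFrame:
    """Classify every call as stringent, relaxed, or absent.

    Step 1 marks calls passing the stringent per-mark cutoff.  Step 2 marks a
    call enriched (provenance ``relaxed``) if it passes the relaxed cutoff
    and overlaps — at the same position or through the ortholog map — a
    step-1 region from any other individual of any species.  Step 2 is a
    single pass against the union of step-1 regions; relaxed calls never seed
    further relaxed calls.

    Returns the input table with an added ``status`` column
    (``stringent`` | ``relaxed`` | ``absent``) and boolean ``enriched``.
    """
    policy = policy or CutoffPolicy()
    _validate_confidence(calls)
    out = calls.copy().reset_index(drop=True)
    status = np.full(len(out), "absent", dtype=object)

    has_species = "species" in out.columns
    ortho_trees = (
        _ortholog_projection_trees(ortholog_map)
        if ortholog_map is not None and has_species
        else {}
    )

    for mark, df in out.groupby("mark"):
        conf = df["confidence"].to_numpy(dtype=float)
        stringent = policy.passes_stringent(mark, conf)
        relaxed = policy.passes_relaxed(mark, conf)
        status[df.index[stringent]] = "stringent"

        seeds = df.loc[stringent]
        if seeds.empty:
            continue

        # stringent footprint per (species, chrom), every entry tagged with
        # the calling individual; seeds are projected into the other genomes
        # through the ortholog map so cross-species overlap is positional
        trees: dict = {}

        def _add(sp, chrom, s, e, individual):
            if e > s:
                trees.setdefault((sp, chrom), IntervalTree()).addi(
                    int(s), int(e), individual
                )

        for rec in seeds.itertuples(index=False):
            sp = rec.species if has_species else ""
            _add(sp, rec.chrom, rec.start, rec.end, rec.individual_id)
            if has_species:
                for side in ("a", "b"):
                    tr = ortho_trees.get((sp, rec.chrom, side))
                    if tr is None:
                        continue
                    for iv in tr.overlap(int(rec.start), int(rec.end)):
                        sp_o, ch_o, s_o, e_o = iv.data
                        _add(sp_o, ch_o, s_o, e_o, rec.individual_id)

        cand = df.index[relaxed & ~stringent]
        for idx in cand:
            rec = out.loc[idx]
            sp = rec["species"] if has_species else ""
            tree = trees.get((sp, rec["chrom"]))
            if tree is None:
                continue
            hits = tree.overlap(int(rec["start"]), int(rec["end"]))
            if any(iv.data != rec["individual_id"] for iv in hits):
                status[idx] = "relaxed"

    out["status"] = status
    out["enriched"] = out["status"] != "absent"
    return out


def _ortholog_projection_trees(ortholog_map: pd.DataFrame) -> dict:
    """Per (species, chrom, side) trees mapping intervals to their orthologs."""
    trees: dict = {}
    for side, other in (("a", "b"), ("b", "a")):
        sp_c, ch_c = f"species_{side}", f"chrom_{side}"
        for (sp, chrom), sub in ortholog_map.groupby([sp_c, ch_c]):
            tree = trees.setdefault((sp, chrom, side), IntervalTree())
            for row in sub.itertuples(index=False):
                s = getattr(row, f"start_{side}")
                e = getattr(row, f"end_{side}")
                if e > s:
                    tree.addi(
                        int(s),
                        int(e),
                        (
                            getattr(row, f"species_{other}"),
                            getattr(row, f"chrom_{other}"),
                            int(getattr(row, f"start_{other}")),
                            int(getattr(row, f"end_{other}")),
                        ),
                    )
    return trees
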