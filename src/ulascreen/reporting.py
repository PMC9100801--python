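"""Cross-cell-line intersection of validated hits and report assembly.

Features validated as anchorage-independence-specific suppressors
("ULA-norm-Ad") in each cell line are intersected; features present in at
least ``min_lines`` cell lines are the screen's final hits.  Feature ids are
compared case-insensitively after trimming, since miRNA nomenclature
capitalization varies between tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = ["OverlapTable", "intersect_hits", "assemble_report", "load_published_overlap"]


def _canon(feature_id: str) -> str:
    return feature_id.strip().lower()


@dataclass
class OverlapTable:
    """Membership of every feature across cell lines plus per-pattern counts.

    ``table`` columns: feature_id, one boolean column per cell line,
    n_lines, overlap_class, final_hit.  ``pattern_counts`` maps the
    frozenset of member cell lines to the number of features showing exactly
    that pattern.
    """

    table: pd.DataFrame
    pattern_counts: dict[frozenset, int]
    min_lines: int

    @property
    def final_hits(self) -> set[str]:
        return set(self.table.loc[self.table["final_hit"], "feature_id"])

    def count(self, *cell_lines: str) -> int:
        """Features whose membership is exactly the given cell lines."""
        return self.pattern_counts.get(frozenset(cell_lines), 0)


def intersect_hits(
    hit_sets: Mapping[str, set[str]], min_lines: int = 2
) -> OverlapTable:
    """Group features by their exact cell-line membership pattern.

    Final hits are features occurring in at least ``min_lines`` sets.
    Ordering is deterministic: pattern size descending, then feature id.
    """
    if not hit_sets:
        raise ValueError("no hit sets supplied")
    lines = sorted(hit_sets)
    # canonical id -> display id (first seen wins) and per-line membership
    display: dict[str, str] = {}
    membership: dict[str, set[str]] = {}
    for line in lines:
        for fid in hit_sets[line]:
            key = _canon(fid)
            display.setdefault(key, fid.strip())
            membership.setdefault(key, set()).add(line)

    rows = []
    counts: dict[frozenset, int] = {}
    for key, members in membership.items():
        counts[frozenset(members)] = counts.get(frozenset(members), 0) + 1
        rows.append(
            {
                "feature_id": display[key],
                **{line: line in members for line in lines},
                "n_lines": len(members),
                "overlap_class": "+".join(sorted(members)),
                "final_hit": len(members) >= min_lines,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["n_lines", "feature_id"], ascending=[False, True], kind="mergesort"
    )
    return OverlapTable(
        table=table.reset_index(drop=True), pattern_counts=counts, min_lines=min_lines
    )


def assemble_report(
    hits: pd.DataFrame | None,
    classifications: Mapping[str, pd.DataFrame] | None,
    overlap: OverlapTable,
    manifest: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Master table joining screen scores, per-cell-line labels and overlap.

    ``hits`` is the primary-screen hit table (or None); ``classifications``
    maps cell line -> label frame from the validation stage.  Feature
    namespaces must agree after canonicalization; unknown validated features
    raise with the offending ids.  Returns the master frame and a manifest
    dict recording configuration for provenance.
    """
    master = overlap.table.copy()
    master["_key"] = master["feature_id"].map(_canon)

    if hits is not None and len(hits):
        h = hits.copy()
        h["_key"] = h["feature_id"].map(_canon)
        unknown = set(master["_key"]) - set(h["_key"])
        if unknown:
            names = sorted(
                master.loc[master["_key"].isin(unknown), "feature_id"]
            )
            raise ValueError(f"validated features absent from the screen table: {names}")
        master = master.merge(
            h[["_key", "viability_score", "q_value"]], on="_key", how="left"
        )
    if classifications:
        for line, frame in classifications.items():
            f = frame.copy()
            f["_key"] = f["feature_id"].map(_canon)
            master = master.merge(
                f[["_key", "label"]].rename(columns={"label": f"label_{line}"}),
                on="_key",
                how="left",
            )
    master = master.drop(columns="_key")

    run_manifest = {
        "min_lines": overlap.min_lines,
        "n_final_hits": int(master["final_hit"].sum()),
        "pattern_counts": {
            "+".join(sorted(k)): v for k, v in overlap.pattern_counts.items()
        },
    }
    if manifest:
        run_manifest.update(manifest)
    return master, run_manifest


def load_published_overlap() -> dict[str, set[str]]:
    """Per-cell-line validated hit sets from a published cervical-cancer
    miRNA-mimic screen, packaged as a fixture table.

    Returns a mapping cell line -> set of validated suppressor feature ids,
    reconstructed from the table's membership labels.
    """
    with resources.files("ulascreen.data").joinpath(
        "published_overlap_hits.tsv"
    ).open() as fh:
        table = pd.read_csv(fh, sep="\t")
    sets: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        for line in row["cell_lines"].split(";"):
            sets.setdefault(line, set()).add(row["feature_id"])
    return sets
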