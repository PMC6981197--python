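"""Conservation prioritisation: rank unprotected sites by lineage diversity."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConservationReport", "top_unprotected"]


@dataclass
class ConservationReport:
    """Unprotected sites ranked by LD, with the selected top fraction."""

    ranked: pd.DataFrame  # rank, site_id, lon, lat, map_mm, ld, protected
    top_set: list[str]
    fraction: float
    threshold_ld: float
    n_unprotected_valid: int

    def to_json(self) -> str:
        return json.dumps({
            "fraction": self.fraction,
            "threshold_ld": self.threshold_ld,
            "n_unprotected_valid": self.n_unprotected_valid,
            "top_set": self.top_set,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str, ranked: pd.DataFrame) -> "ConservationReport":
        d = json.loads(text)
        return cls(ranked=ranked, top_set=d["top_set"], fraction=d["fraction"],
                   threshold_ld=d["threshold_ld"],
                   n_unprotected_valid=d["n_unprotected_valid"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.ranked.to_csv(outdir / "conservation_rank.csv", index=False)
        (outdir / "conservation_summary.json").write_text(self.to_json())


def top_unprotected(ld_table: pd.DataFrame, sites: pd.DataFrame, fraction: float,
                    denominator: str = "unprotected") -> ConservationReport:
    """The top ``fraction`` of unprotected sites by lineage diversity.

    Only sites with a valid LD (flag ``ok``) and protection flag 0 are
    ranked, descending by LD with site-id lexicographic tie-break.  The
    top-set size is ``ceil(fraction * n)`` where n is the count of
    unprotected valid sites (``denominator='all'`` instead uses all valid
    sites for n, still selecting unprotected ones).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if "protected" not in sites.columns:
        raise ValueError("site table lacks a 'protected' column")
    merged = ld_table.reset_index().merge(sites, on="site_id", how="left", validate="1:1")
    valid = merged[(merged["flag"] == "ok") & merged["ld"].notna()]
    unprot = valid[valid["protected"] == 0]
    if unprot.empty:
        raise ValueError("no unprotected site with a valid LD")
    n = len(valid) if denominator == "all" else len(unprot)
    n_top = math.ceil(fraction * n)
    ranked = unprot.sort_values(["ld", "site_id"], ascending=[False, True],
                                kind="mergesort").reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    cols = [c for c in ("rank", "site_id", "lon", "lat", "map_mm", "ld", "protected")
            if c in ranked.columns]
    top = ranked.head(n_top)
    return ConservationReport(
        ranked=ranked[cols],
        top_set=top["site_id"].tolist(),
        fraction=fraction,
        threshold_ld=float(top["ld"].iloc[-1]),
        n_unprotected_valid=len(unprot),
    )
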