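"""Integration of hashtag and genotype demultiplexing calls.

The consensus rule keeps a nucleus when both methods confidently agree,
discards HTO singlets that the genotype contradicts, and *rescues*
nuclei the hashtags missed (HTO doublet or negative) whenever the
genotype assigns them confidently to a single donor.  The yield report
quantifies the gain of the integrated set over either method alone.

The hashtag→donor correspondence is taken from a tag→sample map (one
hashtag per pooled sample); genotype donors map to samples directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genotype import GenotypeCall
from .hto import HTOCall

STATUSES = (
    "concordant_assigned",
    "discordant_discarded",
    "genotype_rescued",
    "unassigned",
)


@dataclass
class ConsensusAssignment:
    barcode: str
    hto_call: str
    hto_sample: str | None
    geno_call: str
    geno_sample: str | None
    final_sample: str | None
    status: str


def integrate_calls(
    hto_calls: list[HTOCall],
    geno_calls: list[GenotypeCall],
    tag_to_sample: dict[str, str] | None = None,
    donor_to_sample: dict[str, str] | None = None,
    lenient: bool = False,
    missing: str = "error",
) -> list[ConsensusAssignment]:
    """Apply the consensus rule per barcode.

    Rule: (a) HTO singlet and genotype singlet to the same sample →
    ``concordant_assigned``; (b) conflicting singlets, or a genotype
    doublet → ``discordant_discarded``; (c) HTO doublet/negative with a
    genotype singlet → ``genotype_rescued``; (d) otherwise →
    ``unassigned``; (e) HTO singlet with an unassigned genotype →
    discarded in strict mode (default), kept in ``lenient`` mode.

    ``missing`` controls barcodes present in only one call list:
    ``"error"`` (default) raises; ``"outer"`` treats the absent method
    as unassigned/negative.
    """
    tag_to_sample = tag_to_sample or {}
    donor_to_sample = donor_to_sample or {}
    hmap = {c.barcode: c for c in hto_calls}
    gmap = {c.barcode: c for c in geno_calls}
    if missing == "error":
        only = set(hmap) ^ set(gmap)
        if only:
            raise ValueError(
                f"{len(only)} barcodes present in only one call list "
                "(pass missing='outer' to treat the absent method as negative)"
            )
        barcodes = [c.barcode for c in hto_calls]
    elif missing == "outer":
        barcodes = [c.barcode for c in hto_calls]
        barcodes += [c.barcode for c in geno_calls if c.barcode not in hmap]
    else:
        raise ValueError(f"unknown missing policy {missing!r}")

    out: list[ConsensusAssignment] = []
    for bc in barcodes:
        h = hmap.get(bc)
        g = gmap.get(bc)
        h_call = h.call if h else "negative"
        g_call = g.call if g else "unassigned"
        h_sample = (
            tag_to_sample.get(h.assigned_tag, h.assigned_tag)
            if h and h.assigned_tag
            else None
        )
        g_sample = (
            donor_to_sample.get(g.assigned_donor, g.assigned_donor)
            if g and g.assigned_donor
            else None
        )

        if h_call == "singlet" and g_call == "singlet":
            if h_sample == g_sample:
                status, final = "concordant_assigned", h_sample
            else:
                status, final = "discordant_discarded", None
        elif g_call == "doublet":
            status, final = "discordant_discarded", None
        elif h_call in ("doublet", "negative") and g_call == "singlet":
            status, final = "genotype_rescued", g_sample
        elif h_call == "singlet" and g_call == "unassigned":
            if lenient:
                status, final = "concordant_assigned", h_sample
            else:
                status, final = "discordant_discarded", None
        else:
            status, final = "unassigned", None
        out.append(
            ConsensusAssignment(bc, h_call, h_sample, g_call, g_sample, final, status)
        )
    return out


@dataclass
class YieldReport:
    n_hto_only: int
    n_geno_only: int
    n_integrated: int
    gain_over_hto_pct: float | None
    gain_over_geno_pct: float | None
    per_sample: pd.DataFrame

    def summary(self) -> str:
        lines = [
            f"HTO-only singlets:        {self.n_hto_only}",
            f"Genotype-only singlets:   {self.n_geno_only}",
            f"Integrated assignments:   {self.n_integrated}",
            f"Gain over HTO-only:       {self.gain_over_hto_pct}%",
            f"Gain over genotype-only:  {self.gain_over_geno_pct}%",
        ]
        if len(self.per_sample):
            counts = self.per_sample["n_nuclei"]
            lines.append(
                f"Per-sample: mean {counts.mean():.0f}, "
                f"range {counts.min()} - {counts.max()}"
            )
        return "\n".join(lines)


def _gain(n_integrated: int, n_base: int) -> float | None:
    if n_base == 0:
        return None
    return round(100.0 * (n_integrated - n_base) / n_base, 1)


def yield_metrics(assignments: list[ConsensusAssignment]) -> YieldReport:
    """Integrated-yield accounting.

    Bases: ``n_hto_only`` = barcodes the hashtags alone would keep (HTO
    singlets); ``n_geno_only`` = barcodes genotypes alone would keep
    (genotype singlets); ``n_integrated`` = barcodes with a final sample.
    Percent gains are 100·(integrated − base)/base to one decimal.
    """
    if not assignments:
        raise ValueError("no assignments")
    n_hto = sum(a.hto_call == "singlet" for a in assignments)
    n_geno = sum(a.geno_call == "singlet" for a in assignments)
    n_int = sum(a.final_sample is not None for a in assignments)
    assigned = pd.DataFrame(
        {
            "sample": [a.final_sample for a in assignments if a.final_sample],
        }
    )
    per_sample = (
        assigned.value_counts("sample").rename("n_nuclei").reset_index()
        if len(assigned)
        else pd.DataFrame(columns=["sample", "n_nuclei"])
    )
    return YieldReport(
        n_hto_only=n_hto,
        n_geno_only=n_geno,
        n_integrated=n_int,
        gain_over_hto_pct=_gain(n_int, n_hto),
        gain_over_geno_pct=_gain(n_int, n_geno),
        per_sample=per_sample,
    )


def assignments_to_frame(assignments: list[ConsensusAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "barcode": [a.barcode for a in assignments],
            "hto_call": [a.hto_call for a in assignments],
            "hto_sample": [a.hto_sample for a in assignments],
            "geno_call": [a.geno_call for a in assignments],
            "geno_sample": [a.geno_sample for a in assignments],
            "final_sample": [a.final_sample for a in assignments],
            "status": [a.status for a in assignments],
        }
    )
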