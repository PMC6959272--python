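"""Per-sample and cohort-level CNV burden accounting.

Burden is the merged covered base pairs per class and sample. The DEL
class includes homozygous deletions (CN=0 is a deletion), so hd_bp is a
subset of del_bp and the cohort total is reported as the sum of the DEL
and DUP means with HD reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .intervals import covered_bp
from .io_formats import CnvCall


@dataclass(frozen=True)
class SampleBurden:
    sample_id: str
    del_bp: int
    dup_bp: int
    hd_bp: int


def sample_burden(calls: Sequence[CnvCall]) -> SampleBurden:
    """Burden of one sample: merged covered bp per class."""
    if not calls:
        raise ValueError("sample_burden requires at least one call")
    sids = {c.sample_id for c in calls}
    if len(sids) != 1:
        raise ValueError(f"calls belong to several samples: {sorted(sids)[:3]}")
    per_class: dict[str, dict[str, list]] = {"DEL": {}, "DUP": {}, "HD": {}}
    for c in calls:
        for cls in ("DEL", "DUP", "HD"):
            if c.matches_class(cls):
                per_class[cls].setdefault(c.chrom, []).append((c.start, c.end))
    bp = {
        cls: sum(covered_bp(np.array(v)) for v in d.values())
        for cls, d in per_class.items()
    }
    return SampleBurden(sids.pop(), del_bp=bp["DEL"], dup_bp=bp["DUP"], hd_bp=bp["HD"])


def cohort_burdens(
    calls: Sequence[CnvCall], sample_ids: Optional[Iterable[str]] = None
) -> list[SampleBurden]:
    """Per-sample burdens; samples without calls get zero burden."""
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    ids = list(sample_ids) if sample_ids is not None else sorted(by_sample)
    out = []
    for sid in ids:
        if sid in by_sample:
            out.append(sample_burden(by_sample[sid]))
        else:
            out.append(SampleBurden(sid, 0, 0, 0))
    return out


def cohort_burden_summary(burdens: Sequence[SampleBurden], n_bins: int = 40) -> dict:
    """Cohort means, total = mean DEL + mean DUP, log10 histograms and the
    deletion-vs-duplication joint density grid."""
    if not burdens:
        raise ValueError("cohort_burden_summary requires at least one sample")
    del_bp = np.array([b.del_bp for b in burdens], dtype=float)
    dup_bp = np.array([b.dup_bp for b in burdens], dtype=float)
    hd_bp = np.array([b.hd_bp for b in burdens], dtype=float)
    mean_del = float(del_bp.mean())
    mean_dup = float(dup_bp.mean())
    summary = {
        "n_samples": len(burdens),
        "mean_del_bp": mean_del,
        "mean_dup_bp": mean_dup,
        "mean_hd_bp": float(hd_bp.mean()),
        "mean_total_bp": mean_del + mean_dup,
        "histograms": {},
    }
    log_all = {}
    for name, arr in (("DEL", del_bp), ("DUP", dup_bp), ("HD", hd_bp)):
        nz = arr[arr > 0]
        if nz.size == 0:
            summary["histograms"][name] = {"counts": [], "edges": []}
            continue
        log_all[name] = np.log10(nz)
        counts, edges = np.histogram(log_all[name], bins=n_bins)
        summary["histograms"][name] = {"counts": counts.tolist(), "edges": edges.tolist()}
    both = (del_bp > 0) & (dup_bp > 0)
    if both.any():
        grid, xe, ye = np.histogram2d(
            np.log10(del_bp[both]), np.log10(dup_bp[both]), bins=min(n_bins, 25)
        )
        summary["del_dup_joint"] = {
            "counts": grid.tolist(),
            "del_edges": xe.tolist(),
            "dup_edges": ye.tolist(),
        }
    return summary


def plot_burden_histogram(burdens: Sequence[SampleBurden], path) -> None:
    """Optional log10 per-sample burden histogram (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, arr, color in (
        ("DEL", [b.del_bp for b in burdens], "tab:red"),
        ("DUP", [b.dup_bp for b in burdens], "tab:blue"),
        ("HD", [b.hd_bp for b in burdens], "tab:purple"),
    ):
        vals = np.array(arr, dtype=float)
        vals = vals[vals > 0]
        if vals.size:
            ax.hist(np.log10(vals), bins=40, histtype="step", label=name, color=color)
    ax.set_xlabel("per-sample burden, log10 bp")
    ax.set_ylabel("samples")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
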