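"""Retrieval statistics for labeled screens: ROC/AUC, sensitivity,
enrichment factors, reconstruction of partially specified rank lists, and
the Cheng-Prusoff conversion.

AUC uses the rank-sum (Mann-Whitney) estimator — the probability that a
randomly chosen active outranks a randomly chosen decoy, ties counting
one half — which coincides with the trapezoidal area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .ranking import RankedScreen

DEFAULT_EF_FRACTIONS = (0.01, 0.05)


@dataclass
class RocResult:
    auc: float
    sensitivity_at_threshold: float
    n_hits: int
    n_fp: int
    ef: dict[float, float]
    curve: list[tuple[float, float]]  # (fpr, tpr)

    @property
    def auc_rounded(self) -> float:
        """AUC at two-decimal reporting precision."""
        return round(self.auc, 2)


@dataclass(frozen=True)
class PartialRankList:
    """A ranked screen known only through summary positions: a top block of
    mostly actives, the decoy ranks inside it, and straggler active ranks."""

    total_actives: int
    total_decoys: int
    listed_decoy_ranks: tuple[int, ...]
    straggler_active_ranks: tuple[int, ...]
    top_block_size: int

    def __post_init__(self) -> None:
        ld = self.listed_decoy_ranks
        st = self.straggler_active_ranks
        if list(ld) != sorted(set(ld)) or list(st) != sorted(set(st)):
            raise ValueError("rank lists must be strictly increasing")
        if any(r <= self.top_block_size for r in st):
            raise ValueError("straggler actives must lie beyond the top block")
        if any(r < 1 for r in ld + st):
            raise ValueError("ranks are 1-based")
        n_total = self.total_actives + self.total_decoys
        if any(r > n_total for r in ld + st):
            raise ValueError("rank beyond list length")
        if self.implied_actives_in_block + len(st) != self.total_actives:
            raise ValueError(
                "inconsistent rank list: block actives + stragglers != total actives"
            )

    @property
    def decoys_in_block(self) -> int:
        return sum(1 for r in self.listed_decoy_ranks if r <= self.top_block_size)

    @property
    def implied_actives_in_block(self) -> int:
        return self.top_block_size - self.decoys_in_block

    def materialize(self) -> list[str]:
        """Full label vector (index 0 = rank 1): actives fill the top block
        except at listed decoy ranks, stragglers sit at their ranks, decoys
        everywhere else."""
        n = self.total_actives + self.total_decoys
        labels = ["decoy"] * n
        decoy_ranks = set(self.listed_decoy_ranks)
        for r in range(1, self.top_block_size + 1):
            if r not in decoy_ranks:
                labels[r - 1] = "active"
        for r in self.straggler_active_ranks:
            labels[r - 1] = "active"
        assert labels.count("active") == self.total_actives
        return labels


def roc(screen: RankedScreen, ef_fractions: tuple[float, ...] = DEFAULT_EF_FRACTIONS) -> RocResult:
    """ROC summary of a labeled ranked screen.

    Entries labeled ``unknown`` are ignored. Requires at least one active
    and one decoy. The "threshold" sensitivity treats every scored entry in
    the list as a hit (appropriate for hit lists already truncated by the
    screen itself).
    """
    labeled = [e for e in screen if e.label in {"active", "decoy"}]
    y = np.array([1 if e.label == "active" else 0 for e in labeled])
    if len(np.unique(y)) < 2:
        raise ValueError("need both actives and decoys to compute a ROC curve")
    scores = np.array([e.score for e in labeled])
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    n_act = int(y.sum())
    n_dec = len(y) - n_act
    n_hits = len(labeled)
    n_recovered = n_act
    ef = {}
    n_total = len(labeled)
    order = np.lexsort((np.array([e.id for e in labeled]), -scores))
    y_sorted = y[order]
    for f in ef_fractions:
        n_f = max(1, int(round(f * n_total)))
        tp_f = int(y_sorted[:n_f].sum())
        ef[f] = (tp_f / n_f) / (n_act / n_total)
    return RocResult(
        auc=auc,
        sensitivity_at_threshold=n_recovered / n_act,
        n_hits=n_hits,
        n_fp=n_dec,
        ef=ef,
        curve=list(zip(fpr.tolist(), tpr.tolist())),
    )


def brute_force_auc(screen: RankedScreen) -> float:
    """Independent pairwise AUC: fraction of (active, decoy) pairs where the
    active scores higher, ties counting one half."""
    actives = [e.score for e in screen if e.label == "active"]
    decoys = [e.score for e in screen if e.label == "decoy"]
    if not actives or not decoys:
        raise ValueError("need both actives and decoys")
    wins = sum(1.0 if a > d else 0.5 if a == d else 0.0 for a in actives for d in decoys)
    return wins / (len(actives) * len(decoys))


def confusion_stats(n_recovered: int, n_actives: int, n_hits: int) -> dict:
    """Sensitivity (whole-percent rounding) and false-positive count of a
    hit list containing ``n_recovered`` of ``n_actives`` true actives."""
    if n_actives < 1:
        raise ValueError("n_actives must be >= 1")
    if n_recovered > n_actives or n_recovered > n_hits or n_recovered < 0:
        raise ValueError("n_recovered must not exceed n_actives or n_hits")
    sens = 100.0 * n_recovered / n_actives
    return {
        "sensitivity_percent": int(round(sens)),
        "sensitivity_exact": sens,
        "n_fp": n_hits - n_recovered,
    }


def auc_from_partial_ranks(p: PartialRankList) -> float:
    """Exact rank-sum AUC of the materialized label vector.

    Internally rational: with ranks 1..N and no score ties, the estimator is
    1 - (#discordant pairs) / (n_act * n_dec) where a pair is discordant when
    the decoy outranks the active.
    """
    labels = p.materialize()
    discordant = 0
    actives_seen = 0
    for lab in labels:
        if lab == "active":
            actives_seen += 1
        else:
            discordant += p.total_actives - actives_seen
    auc = 1 - Fraction(discordant, p.total_actives * p.total_decoys)
    return float(auc)


def cheng_prusoff(ic50: float, radioligand_conc: float, kd: float) -> float:
    """Ki = IC50 / (1 + L/Kd) for a competition binding experiment.

    All concentrations share one unit (conventionally nM); L = 0 reduces to
    Ki = IC50.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if kd <= 0:
        raise ValueError("kd must be positive")
    if radioligand_conc < 0:
        raise ValueError("radioligand concentration must be non-negative")
    return ic50 / (1.0 + radioligand_conc / kd)


def plot_roc(results: dict[str, RocResult], path: str) -> None:
    """ROC curve plot (one line per named result) with the random diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, res in results.items():
        xs, ys = zip(*res.curve)
        ax.plot(xs, ys, label=f"{name} (AUC {res.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="random")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
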