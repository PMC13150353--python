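"""Laminar composition tables, ratios and group comparison.

This is the arithmetic that turns classified, counted cells into the study's
reported quantities: per-layer and pooled counts and proportions of neurons,
glia and vascular cells, the non-neuron-to-neuron ratio

    nNNR = (n_glia + n_vascular) / n_neuron

and the glia-to-neuron ratio

    GNR = n_glia / n_neuron.

Two aggregation conventions coexist, mirroring how such tables are printed:
per-layer rows are summarized as mean +/- SD across replicate columns, while
the pooled "all layers" row is the *accumulated* value, recomputed from the
summed counts (not the mean of per-column pooled values).

Group differences are assessed with a from-first-principles two-proportion
z-test on pooled counts plus a percentile bootstrap over replicate columns,
with Holm correction across layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LayerModel",
    "CompositionTable",
    "GroupSummary",
    "assign_layer",
    "tabulate",
    "table_from_counts",
    "aggregate_columns",
    "two_proportion_test",
    "holm_correction",
    "compare_groups",
]

WM_LABEL = "WM"


@dataclass(frozen=True)
class LayerModel:
    """Ordered layer boundaries along the cortical-depth axis.

    ``boundaries_um`` has one more entry than ``labels``; boundary 0 is the
    pia and the last boundary the gray/white matter interface. Boundaries
    are an input annotation (layers are recognized from cytoarchitecture by
    the annotator), never computed here.
    """

    boundaries_um: tuple
    labels: tuple
    axis: int = 1  # depth is the first in-plane axis in (z, y, x) stacks

    def __post_init__(self):
        b = np.asarray(self.boundaries_um, dtype=float)
        if len(b) != len(self.labels) + 1:
            raise ValueError("need n labels and n+1 boundaries")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("layer labels must be unique")
        object.__setattr__(self, "boundaries_um", tuple(float(x) for x in b))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def pooled_label(self) -> str:
        return f"{self.labels[0]}–{self.labels[-1]}"

    @classmethod
    def from_simulation(cls, config) -> "LayerModel":
        """Layer model matching a simulation's generating layer slabs."""
        return cls(boundaries_um=tuple(config.layer_boundaries_um),
                   labels=tuple(l.label for l in config.layers))


def assign_layer(depth_um: float, layer_model: LayerModel) -> str:
    """Label of the half-open interval [b_i, b_{i+1}) containing the depth.

    A depth exactly on a boundary belongs to the deeper layer that starts
    there; depths beyond the white-matter boundary (or above the pia) are
    flagged ``"WM"`` and excluded from tables.
    """
    b = np.asarray(layer_model.boundaries_um)
    if depth_um < b[0] or depth_um >= b[-1]:
        return WM_LABEL
    idx = int(np.searchsorted(b, depth_um, side="right") - 1)
    return layer_model.labels[idx]


# ---------------------------------------------------------------------------
# composition tables
# ---------------------------------------------------------------------------

_COUNT_COLS = ["n_neuron", "n_glia", "n_vascular", "n_total"]
_PROP_COLS = ["p_neuron", "p_glia", "p_vascular"]


@dataclass
class CompositionTable:
    """Per-layer + pooled counts, proportions, nNNR and GNR.

    ``df`` is indexed by layer label with the pooled row last. Ratios are
    stored at full precision; use :meth:`rounded` for the 1-decimal ratio /
    2-decimal proportion display convention. Rows where a ratio is
    undefined (no neurons, or no glia/vascular split) carry NaN and are
    listed in ``flags``.
    """

    df: pd.DataFrame
    pooled_label: str
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self._check_invariants()

    def _check_invariants(self):
        for lab, row in self.df.iterrows():
            props = row[_PROP_COLS].to_numpy(dtype=float)
            if row["n_total"] > 0 and np.isfinite(props).all():
                psum = props.sum()
                assert abs(psum - 1.0) < 1e-9, f"proportions of {lab} sum to {psum}"
            if np.isfinite(row["nNNR"]) and np.isfinite(row["GNR"]):
                assert row["nNNR"] >= row["GNR"] - 1e-12
        layer_rows = self.df.drop(index=self.pooled_label)
        pooled = self.df.loc[self.pooled_label]
        for c in _COUNT_COLS:
            col = layer_rows[c]
            if col.notna().all() and np.isfinite(pooled[c]):
                assert int(col.sum()) == int(pooled[c]), (
                    f"pooled {c} != sum of layer rows")

    @property
    def pooled(self) -> pd.Series:
        return self.df.loc[self.pooled_label]

    def rounded(self) -> pd.DataFrame:
        """Display convention: proportions to 2 decimals, ratios to 1."""
        out = self.df.copy()
        for c in _PROP_COLS:
            out[c] = out[c].round(2)
        for c in ("nNNR", "GNR"):
            out[c] = out[c].round(1)
        return out

    def to_csv(self, path):
        self.df.to_csv(path, index_label="layer")


def _row_from_counts(n_neuron, n_glia=None, n_vascular=None, n_nonneuron=None,
                     volume_mm3=np.nan):
    """One table row; accepts a 3-way split or an unsplit non-neuron count."""
    if n_nonneuron is None:
        if n_glia is None or n_vascular is None:
            raise ValueError("need n_glia+n_vascular or n_nonneuron")
        n_nonneuron = n_glia + n_vascular
    g = np.nan if n_glia is None else n_glia
    v = np.nan if n_vascular is None else n_vascular
    total = n_neuron + n_nonneuron
    row = {
        "n_neuron": n_neuron, "n_glia": g, "n_vascular": v, "n_total": total,
        "p_neuron": n_neuron / total if total else np.nan,
        "p_glia": g / total if total else np.nan,
        "p_vascular": v / total if total else np.nan,
        "nNNR": n_nonneuron / n_neuron if n_neuron else np.nan,
        "GNR": g / n_neuron if n_neuron else np.nan,
        "volume_mm3": volume_mm3,
        "density_per_mm3": total / volume_mm3 if volume_mm3 and np.isfinite(volume_mm3)
        else np.nan,
    }
    return row


def table_from_counts(layer_counts: dict, pooled_label: str | None = None,
                      volume_mm3: float | None = None) -> CompositionTable:
    """Build a table directly from per-layer counts.

    ``layer_counts`` maps layer label to either ``(n_neuron, n_glia,
    n_vascular)`` or ``{"n_neuron": ..., "n_nonneuron": ...}`` when the
    glia/vascular split is unavailable (then GNR is undefined).
    """
    labels = list(layer_counts)
    if pooled_label is None:
        pooled_label = f"{labels[0]}–{labels[-1]}" if len(labels) > 1 else "total"
    if pooled_label in labels:
        pooled_label = f"{pooled_label} (pooled)"
    rows, flags = {}, {}
    tot = {"n_neuron": 0, "n_glia": 0, "n_vascular": 0, "n_nonneuron": 0}
    split = True
    for lab, c in layer_counts.items():
        if isinstance(c, dict):
            kw = dict(n_neuron=c["n_neuron"], n_glia=c.get("n_glia"),
                      n_vascular=c.get("n_vascular"),
                      n_nonneuron=c.get("n_nonneuron"))
        else:
            kw = dict(n_neuron=c[0], n_glia=c[1], n_vascular=c[2])
        rows[lab] = _row_from_counts(**kw)
        tot["n_neuron"] += kw["n_neuron"]
        if kw.get("n_glia") is not None:
            tot["n_glia"] += kw["n_glia"]
            tot["n_vascular"] += kw["n_vascular"]
            tot["n_nonneuron"] += kw["n_glia"] + kw["n_vascular"]
        else:
            split = False
            tot["n_nonneuron"] += kw["n_nonneuron"]
        if kw["n_neuron"] == 0:
            flags[lab] = "ratios undefined (no neurons)"
    vol = np.nan if volume_mm3 is None else float(volume_mm3)
    rows[pooled_label] = _row_from_counts(
        n_neuron=tot["n_neuron"],
        n_glia=tot["n_glia"] if split else None,
        n_vascular=tot["n_vascular"] if split else None,
        n_nonneuron=tot["n_nonneuron"], volume_mm3=vol)
    if not split:
        flags["GNR"] = "undefined without a glia/vascular split"
    df = pd.DataFrame.from_dict(rows, orient="index")
    return CompositionTable(df=df, pooled_label=pooled_label, flags=flags)


def tabulate(classified_cells, layer_model: LayerModel,
             brick=None) -> CompositionTable:
    """Tabulate classified, counted cells into a composition table.

    Cells are layer-assigned by centroid depth; cells flagged beyond the
    white matter are excluded. If ``brick`` is given its volume feeds the
    density column.
    """
    counts = {lab: {"neuron": 0, "glia": 0, "vascular": 0}
              for lab in layer_model.labels}
    n_wm = 0
    for cell in classified_cells:
        depth = float(cell.nucleus.centroid_um[layer_model.axis])
        lab = assign_layer(depth, layer_model)
        if lab == WM_LABEL:
            n_wm += 1
            continue
        counts[lab][cell.cell_class] += 1
    layer_counts = {
        lab: (c["neuron"], c["glia"], c["vascular"]) for lab, c in counts.items()
    }
    vol = brick.volume_mm3 if brick is not None else None
    table = table_from_counts(layer_counts, pooled_label=None, volume_mm3=vol)
    if n_wm:
        table.flags["WM"] = f"{n_wm} cells beyond the white-matter boundary excluded"
    for lab, c in counts.items():
        if sum(c.values()) == 0:
            table.flags[lab] = "empty layer (proportions undefined)"
    return table


# ---------------------------------------------------------------------------
# aggregation across replicate columns
# ---------------------------------------------------------------------------


@dataclass
class GroupSummary:
    """Mean +/- SD of proportions and ratios across replicate columns.

    Per-layer rows are means of per-column values; the pooled row is, by
    default, the accumulated value recomputed from summed counts with the
    SD taken across the per-column pooled values.
    """

    group: str
    mean: pd.DataFrame
    sd: pd.DataFrame
    n_replicates: int
    pooled_counts: dict
    pooled_label: str

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate column")


_SUMMARY_COLS = _PROP_COLS + ["nNNR", "GNR"]


def aggregate_columns(tables: list[CompositionTable], group: str = "",
                      policy: str = "pooled_counts") -> GroupSummary:
    """Aggregate replicate column tables into a group summary.

    ``policy="pooled_counts"`` (default) recomputes the pooled row from the
    summed counts — the accumulated-value convention; ``policy=
    "mean_of_columns"`` instead averages the per-column pooled rows. The
    per-layer rows are mean +/- SD across columns under either policy.
    """
    if not tables:
        raise ValueError("need at least one replicate table")
    if policy not in ("pooled_counts", "mean_of_columns"):
        raise ValueError(f"unknown policy {policy!r}")
    ref = tables[0]
    layout = list(ref.df.index)
    for t in tables[1:]:
        if list(t.df.index) != layout:
            raise ValueError("replicate tables have mismatched layer sets")

    stack = np.stack([t.df[_SUMMARY_COLS].to_numpy(dtype=float) for t in tables])
    mean = pd.DataFrame(stack.mean(axis=0), index=layout, columns=_SUMMARY_COLS)
    sd = pd.DataFrame(stack.std(axis=0, ddof=0), index=layout,
                      columns=_SUMMARY_COLS)

    pooled_counts = {
        c: float(np.nansum([t.pooled[c] for t in tables]))
        for c in _COUNT_COLS
    }
    if policy == "pooled_counts":
        n_non = pooled_counts["n_total"] - pooled_counts["n_neuron"]
        row = _row_from_counts(
            n_neuron=pooled_counts["n_neuron"],
            n_glia=pooled_counts["n_glia"] if np.isfinite(pooled_counts["n_glia"])
            else None,
            n_vascular=pooled_counts["n_vascular"]
            if np.isfinite(pooled_counts["n_vascular"]) else None,
            n_nonneuron=n_non)
        for c in _SUMMARY_COLS:
            mean.loc[ref.pooled_label, c] = row[c]
    return GroupSummary(group=group, mean=mean, sd=sd,
                        n_replicates=len(tables), pooled_counts=pooled_counts,
                        pooled_label=ref.pooled_label)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def two_proportion_test(k1: int, n1: int, k2: int, n2: int):
    """Two-sided two-proportion z-test on pooled counts.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    Returns ``(z, p_value)``. Identical proportions give z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group totals must be positive")
    p1, p2 = k1 / n1, k2 / n2
    p = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * norm.sf(abs(z)))


def holm_correction(pvalues):
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def compare_groups(tables_a: list[CompositionTable],
                   tables_b: list[CompositionTable],
                   labels=("A", "B"), n_boot: int = 2000,
                   seed: int = 0) -> dict:
    """Compare the neuron proportion between two groups of replicate columns.

    Pooled counts feed the z-test; a percentile bootstrap over replicate
    columns gives a CI for the difference in pooled neuron proportion; the
    per-layer z-tests are Holm-corrected. Requires >= 2 replicates per
    group for the bootstrap (with fewer, the CI is degenerate and flagged).
    """

    def pooled(tables):
        k = sum(int(t.pooled["n_neuron"]) for t in tables)
        n = sum(int(t.pooled["n_total"]) for t in tables)
        return k, n

    ka, na = pooled(tables_a)
    kb, nb = pooled(tables_b)
    z, p = two_proportion_test(ka, na, kb, nb)

    rng = np.random.default_rng(seed)

    def boot_diff():
        ia = rng.integers(0, len(tables_a), size=len(tables_a))
        ib = rng.integers(0, len(tables_b), size=len(tables_b))
        k1, n1 = pooled([tables_a[i] for i in ia])
        k2, n2 = pooled([tables_b[i] for i in ib])
        if n1 == 0 or n2 == 0:
            return np.nan
        return k1 / n1 - k2 / n2

    diffs = np.array([boot_diff() for _ in range(n_boot)])
    diffs = diffs[np.isfinite(diffs)]
    ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    degenerate_ci = len(tables_a) < 2 or len(tables_b) < 2

    # per-layer comparisons (shared layers only), Holm-corrected
    layers_a = [l for l in tables_a[0].df.index if l != tables_a[0].pooled_label]
    layers_b = [l for l in tables_b[0].df.index if l != tables_b[0].pooled_label]
    shared = [l for l in layers_a if l in layers_b]
    per_layer = {}
    raw_p = []
    for lay in shared:
        k1 = sum(int(t.df.loc[lay, "n_neuron"]) for t in tables_a)
        n1 = sum(int(t.df.loc[lay, "n_total"]) for t in tables_a)
        k2 = sum(int(t.df.loc[lay, "n_neuron"]) for t in tables_b)
        n2 = sum(int(t.df.loc[lay, "n_total"]) for t in tables_b)
        if n1 == 0 or n2 == 0:
            per_layer[lay] = {"z": np.nan, "p": np.nan}
            continue
        zl, pl = two_proportion_test(k1, n1, k2, n2)
        per_layer[lay] = {"z": zl, "p": pl}
        raw_p.append((lay, pl))
    if raw_p:
        adj = holm_correction([p for _, p in raw_p])
        for (lay, _), a in zip(raw_p, adj):
            per_layer[lay]["p_holm"] = float(a)

    return {
        "groups": tuple(labels),
        "pooled": {
            labels[0]: {"n_neuron": ka, "n_total": na, "p_neuron": ka / na},
            labels[1]: {"n_neuron": kb, "n_total": nb, "p_neuron": kb / nb},
        },
        "z": z,
        "p_value": p,
        "diff_p_neuron": ka / na - kb / nb,
        "bootstrap_ci_95": ci,
        "bootstrap_degenerate": degenerate_ci,
        "per_layer": per_layer,
    }
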