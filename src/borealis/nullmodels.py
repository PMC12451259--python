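"""Class-label permutation null models for the borealisation indices.

The null hypothesis is that which species are boreal is irrelevant to plot
turnover: species class labels are reshuffled (by default a permutation,
preserving class frequencies) among all species recorded in a study area
over the whole study period, and BCI/BAI are recomputed per plot under
each of ``n_resamples`` reshuffles (999 by default). A plot is flagged when
its observed index lies strictly outside the simulated mean ± 2 SD.

Null BAI is divided by plot duration, like the observed index, so observed
and simulated values share the %/yr scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from borealis.classification import SpeciesClass, is_boreal_class
from borealis.composition import PlotSeries
from borealis.indices import detect_turnover, _endpoint_covers

ResamplingMode = Literal["permute", "draw"]

DEFAULT_N_RESAMPLES = 999


@dataclass(frozen=True)
class NullDistribution:
    plot: str
    index_kind: Literal["BCI", "BAI"]
    n_resamples: int
    sim_mean: float
    sim_sd: float
    observed: float
    outside_2sd: bool
    seed: int


def study_area_pool(all_series: Sequence[PlotSeries], study_area: str) -> list[str]:
    """All species recorded in a study area across plots and surveys."""
    pool: set[str] = set()
    for series in all_series:
        if series.study_area != study_area:
            continue
        for covers in series.covers.values():
            pool.update(covers.index[covers > 0])
    if not pool:
        raise ValueError(f"empty species pool for study area {study_area!r}")
    return sorted(pool)


def resample_classes(
    pool: Sequence[str],
    class_table: Mapping[str, SpeciesClass],
    rng: np.random.Generator,
    mode: ResamplingMode = "permute",
) -> dict[str, bool]:
    """One random reassignment of boreal / non-boreal labels over a pool.

    ``permute`` shuffles the observed labels without replacement (class
    frequencies preserved); ``draw`` samples each label independently with
    the pool's boreal proportion.
    """
    if not pool:
        raise ValueError("empty species pool")
    labels = np.array([is_boreal_class(class_table[t]) for t in pool])
    if mode == "permute":
        shuffled = rng.permutation(labels)
    elif mode == "draw":
        shuffled = rng.random(len(pool)) < labels.mean()
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    return dict(zip(pool, (bool(v) for v in shuffled)))


def _label_matrix(
    pool: Sequence[str],
    class_table: Mapping[str, SpeciesClass],
    n_resamples: int,
    rng: np.random.Generator,
    mode: ResamplingMode,
) -> np.ndarray:
    """(n_resamples, len(pool)) boolean matrix of permuted boreal labels."""
    labels = np.array([is_boreal_class(class_table[t]) for t in pool])
    if mode == "permute":
        return np.array([rng.permutation(labels) for _ in range(n_resamples)])
    if mode == "draw":
        return rng.random((n_resamples, len(pool))) < labels.mean()
    raise ValueError(f"unknown resampling mode {mode!r}")


def _plot_null(
    series: PlotSeries,
    pool_index: Mapping[str, int],
    label_matrix: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated BCI and BAI vectors for one plot under permuted labels."""
    colonisers, _ = detect_turnover(series)
    if colonisers:
        idx = [pool_index[t] for t in colonisers]
        bci_sim = label_matrix[:, idx].sum(axis=1) / len(colonisers)
    else:
        bci_sim = np.zeros(label_matrix.shape[0])  # zero-coloniser convention

    start, end = _endpoint_covers(series)
    delta = (end - start)
    taxa = [t for t in delta.index if t in pool_index]
    idx = [pool_index[t] for t in taxa]
    deltas = delta[taxa].to_numpy()
    bai_sim = (label_matrix[:, idx] * deltas).sum(axis=1) / series.duration_years
    return bci_sim, bai_sim


def null_distribution(
    series: PlotSeries,
    pool: Sequence[str],
    class_table: Mapping[str, SpeciesClass],
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    mode: ResamplingMode = "permute",
) -> dict[str, NullDistribution]:
    """Null distributions of BCI and BAI for a single plot.

    Returns a dict keyed ``{"BCI": ..., "BAI": ...}``. SD uses the sample
    (n−1) denominator; flagging is strict (exactly 2 SD is not flagged).
    """
    from borealis.indices import compute_bai, compute_bci

    rng = np.random.default_rng(seed)
    pool = list(pool)
    matrix = _label_matrix(pool, class_table, n_resamples, rng, mode)
    pool_index = {t: i for i, t in enumerate(pool)}
    bci_sim, bai_sim = _plot_null(series, pool_index, matrix)
    observed = {
        "BCI": compute_bci(series, class_table)[0],
        "BAI": compute_bai(series, class_table),
    }
    out = {}
    for kind, sims in (("BCI", bci_sim), ("BAI", bai_sim)):
        mean = float(sims.mean())
        sd = float(sims.std(ddof=1))
        obs = observed[kind]
        out[kind] = NullDistribution(
            plot=series.plot,
            index_kind=kind,  # type: ignore[arg-type]
            n_resamples=n_resamples,
            sim_mean=mean,
            sim_sd=sd,
            observed=obs,
            outside_2sd=bool(abs(obs - mean) > 2 * sd),
            seed=seed,
        )
    return out


def null_table(
    all_series: Sequence[PlotSeries],
    class_table: Mapping[str, SpeciesClass],
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    mode: ResamplingMode = "permute",
) -> pd.DataFrame:
    """Null-model results for every plot (one row per plot × index kind).

    Label permutations are drawn per study area — one label matrix shared by
    the area's plots per resample, mirroring a study-area-wide reshuffle —
    with per-area random substreams derived deterministically from ``seed``.
    """
    from borealis.indices import compute_bai, compute_bci

    areas = sorted({s.study_area for s in all_series})
    root = np.random.SeedSequence(seed)
    streams = dict(zip(areas, root.spawn(len(areas))))

    rows = []
    for area in areas:
        area_series = [s for s in all_series if s.study_area == area]
        pool = study_area_pool(all_series, area)
        rng = np.random.default_rng(streams[area])
        matrix = _label_matrix(pool, class_table, n_resamples, rng, mode)
        pool_index = {t: i for i, t in enumerate(pool)}
        for series in area_series:
            bci_sim, bai_sim = _plot_null(series, pool_index, matrix)
            obs = {
                "BCI": compute_bci(series, class_table)[0],
                "BAI": compute_bai(series, class_table),
            }
            for kind, sims in (("BCI", bci_sim), ("BAI", bai_sim)):
                mean = float(sims.mean())
                sd = float(sims.std(ddof=1))
                rows.append(
                    {
                        "plot": series.plot,
                        "subsite": series.subsite,
                        "study_area": area,
                        "index_kind": kind,
                        "n_resamples": n_resamples,
                        "sim_mean": mean,
                        "sim_sd": sd,
                        "observed": obs[kind],
                        "outside_2sd": bool(abs(obs[kind] - mean) > 2 * sd),
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)


def flag_fraction(null_results: pd.DataFrame) -> pd.Series:
    """Fraction of plots flagged outside ±2 SD, per index kind."""
    return null_results.groupby("index_kind")["outside_2sd"].mean()
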