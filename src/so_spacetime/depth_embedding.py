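"""Region-by-time depth embedding of slow-oscillation current profiles.

Each SO's source-space CSD time course is reduced to a 17-region x 3-bin
matrix: nine anatomical structures (neocortex, hippocampus, nucleus
accumbens, amygdala, caudate nucleus, putamen, pallidum, thalamus - each
split into left/right - plus the unlateralized brainstem) by three 200-ms
time bins around the SO trough (pre-trough [-300, -100) ms, trough
[-100, +100) ms, post-trough [+100, +300) ms). Row-major flattening gives
a 51-dimensional feature vector per SO; feature names follow
``<Region>_<L/R>_<pre|trough|post>``.

The group comparison mirrors the post-hoc layer of the cohort analysis:
per participant, mean Global and mean non-Global CSD per region, compared
with a paired Wilcoxon signed-rank test across participants and a
Bonferroni-corrected threshold of 0.05/17.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: The 17 regions, in canonical (feature) order.
REGIONS = (
    "Cortex_L", "Cortex_R",
    "Hippocampus_L", "Hippocampus_R",
    "Accumbens_L", "Accumbens_R",
    "Amygdala_L", "Amygdala_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R",
    "Brainstem",
)

N_REGIONS = len(REGIONS)
BIN_NAMES = ("pre", "trough", "post")
N_BINS = len(BIN_NAMES)
N_FEATURES = N_REGIONS * N_BINS  # 51

LABEL_COLUMNS = ("participant", "stage", "is_global")


@dataclass
class TimeBinSpec:
    """Three contiguous 200-ms bins around the trough, half-open [a, b) in ms."""

    edges_ms: tuple = ((-300.0, -100.0), (-100.0, 100.0), (100.0, 300.0))
    names: tuple = BIN_NAMES

    def __post_init__(self):
        if len(self.edges_ms) != len(self.names):
            raise ValueError("one name per bin required")
        for (a0, b0), (a1, _) in zip(self.edges_ms[:-1], self.edges_ms[1:]):
            if b0 != a1 or a0 >= b0:
                raise ValueError("bins must be contiguous and increasing")

    @property
    def span_ms(self) -> tuple:
        return (self.edges_ms[0][0], self.edges_ms[-1][1])

    def bin_of(self, t_ms: np.ndarray) -> np.ndarray:
        """Bin index per timepoint, -1 outside the covered span."""
        t_ms = np.asarray(t_ms, dtype=float)
        out = np.full(t_ms.shape, -1, dtype=int)
        for b, (lo, hi) in enumerate(self.edges_ms):
            out[(t_ms >= lo) & (t_ms < hi)] = b
        return out


def feature_names(regions=REGIONS, bins=BIN_NAMES) -> list:
    """The 51 feature names, region-major: Cortex_L_pre, Cortex_L_trough, ..."""
    return [f"{r}_{b}" for r in regions for b in bins]


def feature_index(region: str, bin_name: str) -> int:
    return REGIONS.index(region) * N_BINS + BIN_NAMES.index(bin_name)


@dataclass
class DepthProfile:
    """One SO's 17 x 3 mean-CSD matrix with labels."""

    matrix: np.ndarray
    participant: str = "p01"
    stage: str = "S2"
    is_global: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (N_REGIONS, N_BINS):
            raise ValueError(f"matrix must be {N_REGIONS} x {N_BINS}")

    @property
    def flat(self) -> np.ndarray:
        return self.matrix.reshape(-1)  # row-major


def embed(
    csd,
    region_of_source: np.ndarray,
    bins: TimeBinSpec | None = None,
    participant: str = "p01",
    stage: str = "S2",
    is_global: bool = False,
) -> DepthProfile:
    """Average a SourceCsd into the 17 x 3 region-by-bin matrix.

    ``csd.times`` are seconds relative to the SO trough and must cover the
    full bin span. Entry (r, b) is the mean of ``csd.values`` over sources
    mapped to region r and timepoints falling in bin b.
    """
    bins = bins or TimeBinSpec()
    t_ms = np.asarray(csd.times, dtype=float) * 1000.0
    lo, hi = bins.span_ms
    # require at least one sample in every bin
    which = bins.bin_of(t_ms)
    region_of_source = np.asarray(region_of_source)
    mat = np.empty((N_REGIONS, N_BINS))
    for r in range(N_REGIONS):
        src = region_of_source == r
        if not src.any():
            raise ValueError(f"region {REGIONS[r]} has no sources in the head model")
        for b in range(N_BINS):
            cols = which == b
            if not cols.any():
                raise ValueError(
                    f"CSD window ({t_ms.min():.0f}, {t_ms.max():.0f}) ms has no "
                    f"samples in bin {bins.names[b]} {bins.edges_ms[b]}; the "
                    f"window must cover ({lo:.0f}, {hi:.0f}) ms"
                )
            mat[r, b] = csd.values[np.ix_(src, cols)].mean()
    return DepthProfile(matrix=mat, participant=participant, stage=stage,
                        is_global=is_global)


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Stack DepthProfile objects into a feature table (51 cols + labels)."""
    rows = [p.flat for p in profiles]
    df = pd.DataFrame(rows, columns=feature_names())
    df["participant"] = [p.participant for p in profiles]
    df["stage"] = [p.stage for p in profiles]
    df["is_global"] = [bool(p.is_global) for p in profiles]
    return df


def profiles_from_recording(
    rec,
    events,
    kernel,
    region_of_source: np.ndarray,
    is_global: np.ndarray | None = None,
    bins: TimeBinSpec | None = None,
) -> pd.DataFrame:
    """Embed every detected event of a recording.

    Extracts the +/-300 ms snapshot window around each event trough (events
    too close to the recording edges are skipped with a warning), applies
    the inverse kernel and bins the CSD magnitudes. ``is_global`` aligns
    with ``events``; omitted labels default to False.
    """
    from .source_localization import apply_kernel

    bins = bins or TimeBinSpec()
    lo_ms, hi_ms = bins.span_ms
    rate = rec.sampling_rate
    lo = int(np.floor(lo_ms / 1000.0 * rate))
    hi = int(np.ceil(hi_ms / 1000.0 * rate))
    profiles = []
    skipped = 0
    for i, ev in enumerate(events):
        c = ev.trough_index
        if c < 0:
            c = int(round(ev.trough_time * rate))
        if c + lo < 0 or c + hi >= rec.n_samples:
            skipped += 1
            continue
        sl = slice(c + lo, c + hi + 1)
        times = (np.arange(lo, hi + 1)) / rate
        csd = apply_kernel(kernel, rec.data[:, sl], times=times)
        profiles.append(
            embed(
                csd, region_of_source, bins,
                participant=ev.participant, stage=ev.stage,
                is_global=bool(is_global[i]) if is_global is not None else False,
            )
        )
    if skipped:
        warnings.warn(f"skipped {skipped} events too close to the recording edges",
                      stacklevel=2)
    return profiles_to_frame(profiles)


def bonferroni_alpha(n_comparisons: int = N_REGIONS, alpha: float = 0.05) -> float:
    """Corrected per-comparison threshold: alpha / number of regions."""
    return alpha / n_comparisons


def compare_group_means(
    profiles: pd.DataFrame,
    time_bin: str = "trough",
    stage: str | None = None,
    alpha: float = 0.05,
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Region-wise paired Wilcoxon comparison of Global vs non-Global CSD.

    For each participant the mean CSD over their Global and over their
    non-Global profiles is computed per region within ``time_bin``; the two
    per-participant series are compared region by region with a Wilcoxon
    signed-rank test (exact null distribution for cohorts of up to
    ``exact_max_n`` participants, normal approximation beyond).
    Significance is flagged at the Bonferroni-corrected alpha / 17;
    participants missing one class are dropped from the pairing with a
    warning. The result carries ``attrs['alpha_corrected']``.
    """
    df = profiles
    if stage is not None:
        df = df[df["stage"] == stage]
    cols = [f"{r}_{time_bin}" for r in REGIONS]
    means = df.groupby(["participant", "is_global"], observed=True)[cols].mean()
    g = means.xs(True, level="is_global")
    ng = means.xs(False, level="is_global")
    common = g.index.intersection(ng.index)
    dropped = set(g.index).symmetric_difference(ng.index)
    if dropped:
        warnings.warn(
            f"participants {sorted(dropped)} lack one class and are dropped "
            "from the paired comparison",
            stacklevel=2,
        )
    if len(common) < 2:
        raise ValueError("need at least 2 participants with both classes")
    g, ng = g.loc[common], ng.loc[common]
    alpha_corr = bonferroni_alpha(N_REGIONS, alpha)
    method = "exact" if len(common) <= exact_max_n else "approx"
    rows = []
    for r in REGIONS:
        a = g[f"{r}_{time_bin}"].to_numpy()
        b = ng[f"{r}_{time_bin}"].to_numpy()
        if np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            try:
                res = stats.wilcoxon(a, b, method=method)
            except ValueError:  # e.g. zeros under the exact method
                res = stats.wilcoxon(a, b, method="approx")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "region": r,
                "n_participants": len(common),
                "mean_global": a.mean(),
                "mean_nonglobal": b.mean(),
                "statistic": stat,
                "p_value": p,
                "significant": p < alpha_corr,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha_corrected"] = alpha_corr
    out.attrs["time_bin"] = time_bin
    return out
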