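"""Per-spheroid viability feature vector from a baselined plot profile.

The 14 variables fed to the response PCA are, per channel (CAM, PI, TL):
baseline-corrected AUC per μm of diameter, baseline, maximum peak height
and width of the widest peak, plus two geometry fractions: the distance
between the outermost pair of CAM rim peaks and the width of the widest PI
peak, both as percent of the spheroid diameter.  The TL channel is
inverted before peak detection so its light-impermeable core behaves as a
peak; the TL core percent is reported as a derived summary, not among
the 14.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .profiles import PlotProfile

__all__ = ["Peak", "PeakSet", "detect_peaks", "compute_metrics",
           "ViabilityMetrics", "PCA_VARIABLES"]

PCA_VARIABLES = (
    "auc_per_um_cam", "auc_per_um_pi", "auc_per_um_tl",
    "baseline_cam", "baseline_pi", "baseline_tl",
    "peak_height_cam", "peak_height_pi", "peak_height_tl",
    "widest_width_cam", "widest_width_pi", "widest_width_tl",
    "cam_core_pct", "pi_core_pct",
)


@dataclass(frozen=True)
class Peak:
    position_um: float
    height: float          # baseline-corrected intensity at the peak
    prominence: float
    width_um: float        # measured at half prominence


@dataclass
class PeakSet:
    channel: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.position_um)

    def __len__(self) -> int:
        return len(self.peaks)


def _detection_signal(profile: PlotProfile, channel: str) -> np.ndarray:
    """Baseline-corrected signal for peak finding.  TL is inverted first
    (the dark core is an attenuation trough) and re-baselined at the lower
    quartile of the inverted trace."""
    y = profile.intensities[channel]
    if channel == "TL":
        inv = y.max() - y
        return inv - np.percentile(inv, 25)
    if channel not in profile.baselines:
        raise ValueError(f"channel {channel} not baselined")
    return y - profile.baselines[channel]


def detect_peaks(profile: PlotProfile, channel: str,
                 prominence_frac: float = 0.05,
                 min_separation: int = 5) -> PeakSet:
    """Local maxima with prominence >= ``prominence_frac`` of the channel
    maximum and separation >= ``min_separation`` samples; widths at half
    prominence.  An all-zero channel yields an empty PeakSet."""
    if not profile.smoothed:
        raise ValueError("profile must be smoothed before peak detection")
    signal = _detection_signal(profile, channel)
    top = float(signal.max())
    if top <= 0:
        return PeakSet(channel=channel, peaks=[])
    idx, props = find_peaks(signal, prominence=prominence_frac * top,
                            distance=min_separation)
    if idx.size == 0:
        return PeakSet(channel=channel, peaks=[])
    widths_px = peak_widths(signal, idx, rel_height=0.5,
                            prominence_data=(props["prominences"],
                                             props["left_bases"],
                                             props["right_bases"]))[0]
    peaks = [
        Peak(position_um=float(profile.positions_um[i]),
             height=float(signal[i]),
             prominence=float(p),
             width_um=float(w * profile.pixel_size_um))
        for i, p, w in zip(idx, props["prominences"], widths_px)
    ]
    return PeakSet(channel=channel, peaks=peaks)


@dataclass
class ViabilityMetrics:
    """The canonical 14 PCA-input variables plus derived summaries."""

    auc_per_um_cam: float = 0.0
    auc_per_um_pi: float = 0.0
    auc_per_um_tl: float = 0.0
    baseline_cam: float = 0.0
    baseline_pi: float = 0.0
    baseline_tl: float = 0.0
    peak_height_cam: float = 0.0
    peak_height_pi: float = 0.0
    peak_height_tl: float = 0.0
    widest_width_cam: float = 0.0
    widest_width_pi: float = 0.0
    widest_width_tl: float = 0.0
    cam_core_pct: float = 0.0
    pi_core_pct: float = 0.0
    # derived summaries, excluded from the PCA inputs
    cam_rim_pct: float = 0.0       # per-side rim, (100 - cam_core_pct) / 2
    tl_core_pct: float = 0.0
    total_auc_cam: float = 0.0
    total_auc_pi: float = 0.0
    total_auc_tl: float = 0.0
    diameter_um: float = 0.0

    def pca_vector(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PCA_VARIABLES}

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_metrics(profile: PlotProfile, peaks: dict[str, PeakSet],
                    diameter_um: float) -> ViabilityMetrics:
    """Assemble the feature vector from a baselined profile, detected
    peaks, and the spheroid diameter from brightfield segmentation."""
    if diameter_um <= 0:
        raise ValueError("diameter_um must be > 0")
    for ch in ("CAM", "PI", "TL"):
        if ch not in profile.aucs:
            raise ValueError(f"profile missing AUC for channel {ch}; "
                             "run baseline_and_auc first")

    m = ViabilityMetrics(diameter_um=diameter_um)
    for ch, prefix in (("CAM", "cam"), ("PI", "pi"), ("TL", "tl")):
        auc = profile.aucs[ch]
        setattr(m, f"total_auc_{prefix}", auc)
        setattr(m, f"auc_per_um_{prefix}", auc / diameter_um)
        setattr(m, f"baseline_{prefix}", profile.baselines[ch])
        ps = peaks.get(ch, PeakSet(channel=ch, peaks=[]))
        if len(ps):
            setattr(m, f"peak_height_{prefix}", max(p.height for p in ps.peaks))
            setattr(m, f"widest_width_{prefix}", max(p.width_um for p in ps.peaks))

    cam = peaks.get("CAM", PeakSet(channel="CAM", peaks=[]))
    if len(cam) >= 2:
        span = cam.peaks[-1].position_um - cam.peaks[0].position_um
        m.cam_core_pct = float(np.clip(100.0 * span / diameter_um, 0.0, 100.0))
        m.cam_rim_pct = (100.0 - m.cam_core_pct) / 2.0

    pi = peaks.get("PI", PeakSet(channel="PI", peaks=[]))
    if len(pi):
        widest = max(p.width_um for p in pi.peaks)
        m.pi_core_pct = float(np.clip(100.0 * widest / diameter_um, 0.0, 100.0))

    tl = peaks.get("TL", PeakSet(channel="TL", peaks=[]))
    if len(tl):
        widest = max(p.width_um for p in tl.peaks)
        m.tl_core_pct = float(np.clip(100.0 * widest / diameter_um, 0.0, 100.0))
    return m
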