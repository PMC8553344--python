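"""Analysis configuration: every named constant of the pipeline in one place.

Defaults equal the protocol's stated constants: 10 kHz sampling, 1 ms
convolution kernel, 100 ms Hamming / 95% overlap Welch windows,
95th-percentile ridge thresholds over 40-200 Hz with a 150 Hz/ms
continuity limit, +/-5 ms spike and +/-1 ms IPSC synchrony windows, the
2.5x-SD IPSC amplitude rule, the 10-150 Hz / 30 Hz/ms / 20%-deviation /
2-period STO rules with the >= 10-event resonance threshold, and the
50-500 pA (10 x 50 pA) step protocol.  A stable hash of the configuration
is recorded in every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass(frozen=True)
class AnalysisConfig:
    fs: float = 10_000.0
    kernel_sigma: float = 0.001
    # Welch spectrogram
    welch_window: float = 0.100
    welch_overlap: float = 0.95
    welch_taper: str = "hamming"
    theta_window: float = 0.500
    theta_band: tuple = (2.0, 12.0)
    # ridge detection
    ridge_band: tuple = (40.0, 200.0)
    ridge_percentile: float = 95.0
    ridge_continuity: float = 150.0  # Hz/ms
    ridge_min_bins: int = 2
    # synchrony windows
    dt_spike: float = 0.005
    dt_ipsc: float = 0.001
    w_grid_ms: tuple = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
    # IPSC detection
    ipsc_criterion: float = 3.0
    ipsc_amplitude_sd: float = 2.5
    # surrogates
    n_surrogates: int = 10
    psth_bin: float = 0.001
    psth_sigma: float = 0.001  # surrogate rate-matching resolution
    # STO / resonance
    sto_band: tuple = (10.0, 150.0)
    sto_continuity: float = 30.0  # Hz/ms
    sto_freq_deviation: float = 0.20
    sto_min_periods: float = 2.0
    sto_r2_gate: float = 0.70
    resonance_threshold: int = 10
    step_amplitudes_pa: tuple = tuple(50 * k for k in range(1, 11))
    # randomness
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["config_hash"] = self.hash()
        return d
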