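"""Independent numerical oracles used by the tests (plain numpy only)."""

import numpy as np


def hann_windowed_tone_peak_spl(spec, tone, window_size=2560, hop=60):
    """Independent oracle for the spectrogram's band-SPL convention.

    Plain-numpy Hann-windowed DFT power of the analytically synthesised tone
    at its own frequency bin, maximised over window positions; no
    scipy.signal involved.
    """
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    t = (np.arange(n) - spec.trigger_index) / fs
    tau = t - tone.onset_s
    sig = np.where(
        tau >= 0,
        tone.amplitude_pa
        * np.exp(-tone.decay_per_s * np.clip(tau, 0, None))
        * np.sin(2 * np.pi * tone.frequency_hz * tau),
        0.0,
    )
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(window_size) / window_size)
    k = int(round(tone.frequency_hz * window_size / fs))
    phase = np.exp(-2j * np.pi * k * np.arange(window_size) / window_size)
    best = -np.inf
    for start in range(0, n - window_size + 1, hop):
        X = phase @ (sig[start : start + window_size] * w)
        best = max(best, 2.0 * abs(X) ** 2 / w.sum() ** 2)
    return 10.0 * np.log10(best / 1e-12)
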