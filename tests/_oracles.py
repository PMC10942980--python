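"""Independent analytic oracles used only by the test suite."""


def butter_bidirectional_gain(f, cutoff, order=4):
    """Analytic amplitude response of a forward-backward Butterworth
    low-pass filter: |H|^2 of the single pass."""
    return 1.0 / (1.0 + (f / cutoff) ** (2 * order))
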