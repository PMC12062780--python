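"""Physical constants shared across modules."""

# Average-mass proton, Da — the native-MS charging convention used for
# converting between m/z and neutral mass.
PROTON_MASS = 1.00728
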