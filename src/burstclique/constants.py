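"""Single-neuron constants shared across the package.

All potentials and currents are expressed in mV (the membrane input
resistance is folded into the currents), all times in ms.
"""

#: membrane time constant, ms
TAU_M = 30.0

#: reset potential after a spike, mV
V_R = 13.5

#: firing threshold, mV
V_TH = 15.0
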