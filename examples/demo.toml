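# End-to-end demo: generate a two-population burst scenario, detect bursts,
# build the stoichiometry-filtered histogram, decompose it into populations,
# and fit a two-state denaturant titration.
#
#   fretscape run --config examples/demo.toml --outdir demo_run

[run]
seed = 11
outdir = "demo_run"

[setup]
r0_nm = 5.4
gamma = 1.0

[scenario]
n_bursts = 1500
donor_only_fraction = 0.15
populations = [
  { name = "folded", kind = "fixed_efficiency", e = 0.9, weight = 0.5 },
  { name = "unfolded", kind = "wlc", l_p = 2.5, l_c = 7.7, weight = 0.5 },
]

[bursts]
threshold = 50
max_gap_s = 1e-4

[histogram]
bins = 50
s_window = [0.3, 0.7]

[mixture]
k = 2

[titration]
states = ["U", "F"]
dg0 = [0.0, -5.2]
m = [0.0, 2.524]
concentrations = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5]
noise_sd = 0.03
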