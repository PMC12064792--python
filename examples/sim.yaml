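# A desk-scale simulated survey: the 24 benchmark species with their
# published abundances, planted within-group confusion for the global
# detector, experts at one tenth of those error rates.
seed: 1
n_images: 5000
empty_fraction: 0.3
n_sites: 10
species: benchmark
global:  {within: 0.3, across: 0.01, miss: 0.05}
experts: {within: 0.03, across: 0.001, miss: 0.005}
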