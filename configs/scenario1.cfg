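# Adaptive-tuning comparison on the stiff 100-dimensional Gaussian scenario.
experiment = scenario_adapt
scenario = 1
dim = 100
iterations = 10000
reps = 10
seed = 1
kappa = 0.6
samplers = rwm,mala,barker
checkpoints = 10000
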