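# Simulated analogue of the full benchmark design:
# 10 workflows x 5 protocols x 4 samples (2 patients, tumor/normal),
# minus two unsupported workflow-protocol combinations (each spanning all
# 4 samples) = 192 runs.  n_sites is kept small so the scenario runs at
# desk scale; profiles encode behavioural archetypes, not measurements of
# any real tool.
name: study_design
seed: 20260923
n_sites: 2000
n_dml: 200
effect: 0.3

samples:
  - {id: "P5N", patient: "P5", condition: normal}
  - {id: "P5T", patient: "P5", condition: tumor}
  - {id: "P6N", patient: "P6", condition: normal}
  - {id: "P6T", patient: "P6", condition: tumor}

protocols:
  # one deep standard protocol, three low-input, one enzymatic
  - {name: WGBS,   mean_depth: 43, depth_dispersion: 8.0, gc_skew: 0.0,  conversion_error: 0.005}
  - {name: Swift,  mean_depth: 30, depth_dispersion: 6.0, gc_skew: 0.2,  conversion_error: 0.005}
  - {name: EM-seq, mean_depth: 30, depth_dispersion: 6.0, gc_skew: 0.0,  conversion_error: 0.002}
  - {name: T-WGBS, mean_depth: 12, depth_dispersion: 4.0, gc_skew: 0.3,  conversion_error: 0.005}
  - {name: PBAT,   mean_depth: 8,  depth_dispersion: 1.5, gc_skew: 1.5,  conversion_error: 0.01}

workflows:
  - {name: wf-reference-a,   retention: 0.99}
  - {name: wf-reference-b,   retention: 0.99, noise_sd: 0.01}
  - {name: wf-no-dedup,      retention: 0.99, dedup: false, duplicate_factor: 1.2}
  - {name: wf-mate-double,   retention: 0.99, double_count: true, double_count_fraction: 0.5}
  - {name: wf-underestimate, retention: 0.98, bias: -0.08}
  - {name: wf-overestimate,  retention: 0.98, bias: 0.05}
  - {name: wf-noisy,         retention: 0.97, noise_sd: 0.10}
  - {name: wf-low-retention, retention: 0.80, noise_sd: 0.02}
  - {name: wf-fail-lowinput, retention: 0.90, noise_sd: 0.05}
  - {name: wf-lossy,         retention: 0.85, bias: -0.03, noise_sd: 0.05}

# workflow-protocol combinations absent from the design (each drops 4 runs)
excluded:
  - [wf-no-dedup, PBAT]
  - [wf-fail-lowinput, PBAT]

gold_standard:
  n_loci: 46
  n_technologies: 5
  tech_noise_sd: 0.04
  sites_per_locus: 5
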