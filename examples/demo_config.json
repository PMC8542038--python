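{
  "out_dir": "chromarch_demo",
  "seed": 11,
  "genome": {"n_chroms": 2, "comp_bins": 40, "bin_size": 25000,
             "comp_factor": 20, "tad_factor": 2},
  "synthetic": {"flip_fraction": 0.121, "weaken_fraction": 0.5,
                "loop_loss_fraction": 0.3, "depth": 10000.0, "snr": 5.0,
                "n_genes": 1000, "de_effect": 4.0},
  "model3d": {"n_steps": 1500, "n_restarts": 2}
}
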