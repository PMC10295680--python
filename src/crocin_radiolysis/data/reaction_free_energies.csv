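label,delta_g_ev,lower_bound
Me2-crocetin + OH -> R.Ca,-1.98,0
Me2-crocetin + OH -> R.Cb,-1.94,0
R.Ca + R.Ca -> dimer CaCa,-1.09,0
R.Ca + R.Cb -> dimer CaCb,-1.05,0
R.Cb + R.Cb -> dimer CbCb,-1.12,0
R.Ca + R.Ca -> Me2-crocetin(-2H) CaCa' 1A,-0.26,0
R.Ca + R.Ca -> Me2-crocetin(-2H) CaCa' cyclic,-0.48,0
R.Ca + R.Ca -> Me2-crocetin(-2H) Ca.Cb. 3a,0.30,0
R.Ca + R.Ca -> Me2-crocetin(-2H) Ca.Cb. 1A,0.30,1
R.Ca + R.Ca -> Me2-crocetin(-2H) CaCb cyclic,-1.28,0
R.Ca + R.Ca -> Me2-crocetin(-2H) CaCb' 1A,-0.26,0
R.Ca + R.Ca -> Me2-crocetin(-2H) CaCb' cyclic,-0.39,0
R.Ca + R.Cb -> Me2-crocetin(-2H) CaCa' 1A,-0.30,0
R.Ca + R.Cb -> Me2-crocetin(-2H) CaCa' cyclic,-0.52,0
R.Ca + R.Cb -> Me2-crocetin(-2H) Ca.Cb. 3a,0.26,0
R.Ca + R.Cb -> Me2-crocetin(-2H) Ca.Cb. 1A,0.26,1
R.Ca + R.Cb -> Me2-crocetin(-2H) CaCb cyclic,-1.32,0
R.Ca + R.Cb -> Me2-crocetin(-2H) CaCb' 1A,-0.30,0
R.Ca + R.Cb -> Me2-crocetin(-2H) CaCb' cyclic,-0.43,0
R.Ca + R.Cb -> Me2-crocetin(-2H) CbCb' 1A,-0.29,0
R.Ca + R.Cb -> Me2-crocetin(-2H) CbCb' cyclic,-1.04,0
R.Cb + R.Cb -> Me2-crocetin(-2H) Ca.Cb. 3a,0.22,0
R.Cb + R.Cb -> Me2-crocetin(-2H) Ca.Cb. 1A,0.22,1
R.Cb + R.Cb -> Me2-crocetin(-2H) CaCb cyclic,-1.36,0
R.Cb + R.Cb -> Me2-crocetin(-2H) CaCb' 1A,-0.33,0
R.Cb + R.Cb -> Me2-crocetin(-2H) CaCb' cyclic,-0.47,0
R.Cb + R.Cb -> Me2-crocetin(-2H) CbCb' 1A,-0.33,0
R.Cb + R.Cb -> Me2-crocetin(-2H) CbCb' cyclic,-1.08,0
R.Ca + Me2-crocetin -> complex,-0.52,0
R.Cb + Me2-crocetin -> complex,-0.52,0
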