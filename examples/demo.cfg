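# Demo pipeline configuration: three genotypes at the cytological sample
# sizes of the original study. Run with:
#   meiocross all examples/demo.cfg --out-dir demo_run
schema_version = 1
seed = 1
genotypes = WT,hei10,mer3hei10
n_cells.WT = 130
n_cells.hei10 = 130
n_cells.mer3hei10 = 121
analyses = gof,ttest,interference,coloc
coloc_tolerance = 0.01
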