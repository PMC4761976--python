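"""Two-cohort seed-connectivity study on synthetic data (reduced grid)."""
import seedconn as sc

spec = sc.AcquisitionSpec(nx=40, ny=40, nz=7, n_volumes=300)
atlas = sc.make_toy_atlas(spec, n_rois=25)

cohorts = {}
for profile in (sc.shr_like_profile(), sc.wky_like_profile()):
    truth = sc.build_target_matrix(atlas, profile, spec)
    images, truth = sc.simulate_cohort(truth, n_subjects=9, master_seed=7)
    preprocessed = [sc.preprocess_subject(img) for img in images]

    dmn = sc.SeedDMN(
        [sc.corr_map(proc, sc.roi_timecourse(proc, atlas, "RSC", mask), mask)
         for proc, mask in preprocessed]
    ).fit()
    mats = [sc.subject_conn_matrix(proc, atlas, mask)
            for proc, mask in preprocessed]
    cohorts[profile.name] = (dmn, mats)
    print(dmn.summary())
    print()

net = sc.EdgeNetwork(
    cohorts["SHR-like"][1], cohorts["WKY-like"][1],
    group_a="SHR-like", group_b="WKY-like",
).fit()
print(net.summary())
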