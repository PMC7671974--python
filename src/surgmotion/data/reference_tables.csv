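table,exercise,skill_level,parameter,value,policy
table1,suturing,,n_trials,39,exact
table1,knot_tying,,n_trials,36,exact
table1,needle_passing,,n_trials,28,exact
table1,suturing,novice,grs_mean,17.5,exact
table1,suturing,intermediate,grs_mean,25.1,exact
table1,suturing,expert,grs_mean,16.3,exact
table1,knot_tying,novice,grs_mean,10.7,exact
table1,knot_tying,intermediate,grs_mean,17.1,exact
table1,knot_tying,expert,grs_mean,17.7,exact
table1,needle_passing,novice,grs_mean,16.0,exact
table1,needle_passing,intermediate,grs_mean,14.0,exact
table1,needle_passing,expert,grs_mean,12.4,exact
table1,suturing,novice,grs_sd,4.40,exact
table1,suturing,intermediate,grs_sd,4.09,exact
table1,suturing,expert,grs_sd,3.65,exact
table1,knot_tying,novice,grs_sd,4.19,exact
table1,knot_tying,intermediate,grs_sd,4.28,exact
table1,knot_tying,expert,grs_sd,3.02,exact
table1,needle_passing,novice,grs_sd,5.14,exact
table1,needle_passing,intermediate,grs_sd,6.05,exact
table1,needle_passing,expert,grs_sd,2.35,exact
table1,suturing,,spearman_r,0.104,exact
table1,knot_tying,,spearman_r,0.55,exact
table1,needle_passing,,spearman_r,-0.293,exact
table2,suturing,novice,n,19,exact
table2,suturing,intermediate,n,10,exact
table2,suturing,expert,n,10,exact
table2,knot_tying,novice,n,16,exact
table2,knot_tying,intermediate,n,10,exact
table2,knot_tying,expert,n,10,exact
table2,needle_passing,novice,n,11,exact
table2,needle_passing,intermediate,n,8,exact
table2,needle_passing,expert,n,9,exact
table2,suturing,novice,time_mean,137,exact
table2,suturing,intermediate,time_mean,88.5,exact
table2,suturing,expert,time_mean,101,exact
table2,knot_tying,novice,time_mean,71.5,exact
table2,knot_tying,intermediate,time_mean,47.4,exact
table2,knot_tying,expert,time_mean,44.0,exact
table2,needle_passing,novice,time_mean,118.18,exact
table2,needle_passing,intermediate,time_mean,93.38,exact
table2,needle_passing,expert,time_mean,108.7,exact
table2,suturing,novice,time_sd,49.6,exact
table2,suturing,intermediate,time_sd,14.4,exact
table2,suturing,expert,time_sd,20.0,exact
table2,knot_tying,novice,time_sd,18.9,exact
table2,knot_tying,intermediate,time_sd,18.8,exact
table2,knot_tying,expert,time_sd,5.06,exact
table2,needle_passing,novice,time_sd,16.6,exact
table2,needle_passing,intermediate,time_sd,30.4,exact
table2,needle_passing,expert,time_sd,22.2,exact
table2,suturing,novice,right_path_length_mean,0.290,informational
table2,suturing,intermediate,right_path_length_mean,0.440,informational
table2,suturing,expert,right_path_length_mean,0.500,informational
table2,suturing,novice,right_movements_mean,34.5,informational
table2,suturing,intermediate,right_movements_mean,49.1,informational
table2,suturing,expert,right_movements_mean,47.8,informational
table2,suturing,novice,left_path_length_mean,3.02,informational
table2,suturing,intermediate,left_path_length_mean,3.10,informational
table2,suturing,expert,left_path_length_mean,1.72,informational
table2,suturing,novice,left_movements_mean,40.3,informational
table2,suturing,intermediate,left_movements_mean,63.3,informational
table2,suturing,expert,left_movements_mean,14.7,informational
table2,knot_tying,novice,right_path_length_mean,0.16,informational
table2,knot_tying,intermediate,right_path_length_mean,0.45,informational
table2,knot_tying,expert,right_path_length_mean,0.31,informational
table2,knot_tying,novice,right_movements_mean,21.8,informational
table2,knot_tying,intermediate,right_movements_mean,43.5,informational
table2,knot_tying,expert,right_movements_mean,37.1,informational
table2,knot_tying,novice,left_path_length_mean,1.58,informational
table2,knot_tying,intermediate,left_path_length_mean,2.11,informational
table2,knot_tying,expert,left_path_length_mean,1.02,informational
table2,knot_tying,novice,left_movements_mean,17.0,informational
table2,knot_tying,intermediate,left_movements_mean,20.6,informational
table2,knot_tying,expert,left_movements_mean,13.5,informational
table2,needle_passing,novice,right_path_length_mean,0.26,informational
table2,needle_passing,intermediate,right_path_length_mean,0.50,informational
table2,needle_passing,expert,right_path_length_mean,0.28,informational
table2,needle_passing,novice,right_movements_mean,31.4,informational
table2,needle_passing,intermediate,right_movements_mean,50.0,informational
table2,needle_passing,expert,right_movements_mean,32.1,informational
table2,needle_passing,novice,left_path_length_mean,1.80,informational
table2,needle_passing,intermediate,left_path_length_mean,2.06,informational
table2,needle_passing,expert,left_path_length_mean,1.72,informational
table2,needle_passing,novice,left_movements_mean,13.3,informational
table2,needle_passing,intermediate,left_movements_mean,32.5,informational
table2,needle_passing,expert,left_movements_mean,13.9,informational
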