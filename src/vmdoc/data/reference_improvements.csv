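comparison,task,classifier,value
rel_all_vs_bands,multiclass,knn,33.3
rel_all_vs_raw,multiclass,knn,0
rel_all_vs_bands,multiclass,linear_svm,26.7
rel_all_vs_raw,multiclass,linear_svm,60.6
rel_all_vs_bands,multiclass,decision_tree,69
rel_all_vs_raw,multiclass,decision_tree,83.8
rel_all_vs_bands,multiclass,ensemble_bagged_tree,78.8
rel_all_vs_raw,multiclass,ensemble_bagged_tree,67.0
rel_all_vs_bands,binary,knn,63.5
rel_all_vs_raw,binary,knn,5.8
rel_all_vs_bands,binary,linear_svm,19.9
rel_all_vs_raw,binary,linear_svm,9.1
rel_all_vs_bands,binary,decision_tree,111
rel_all_vs_raw,binary,decision_tree,18.8
rel_all_vs_bands,binary,ensemble_bagged_tree,127
rel_all_vs_raw,binary,ensemble_bagged_tree,38.8
rel_sel_vs_bands,multiclass,knn,45.2
rel_sel_vs_raw,multiclass,knn,38.6
rel_sel_vs_bands,multiclass,linear_svm,43.9
rel_sel_vs_raw,multiclass,linear_svm,116.9
rel_sel_vs_bands,multiclass,decision_tree,10.6
rel_sel_vs_raw,multiclass,decision_tree,4.5
rel_sel_vs_bands,multiclass,ensemble_bagged_tree,50.5
rel_sel_vs_raw,multiclass,ensemble_bagged_tree,61
rel_sel_vs_bands,binary,knn,4.7
rel_sel_vs_raw,binary,knn,29.3
rel_sel_vs_bands,binary,linear_svm,71.3
rel_sel_vs_raw,binary,linear_svm,60
rel_sel_vs_bands,binary,decision_tree,17.6
rel_sel_vs_raw,binary,decision_tree,54
rel_sel_vs_bands,binary,ensemble_bagged_tree,13
rel_sel_vs_raw,binary,ensemble_bagged_tree,62.7
abs_sel_vs_all,multiclass,knn,15.0
abs_sel_vs_all,multiclass,linear_svm,13.5
abs_sel_vs_all,multiclass,decision_tree,-16.0
abs_sel_vs_all,multiclass,ensemble_bagged_tree,4.5
abs_sel_vs_all,binary,knn,13.3
abs_sel_vs_all,binary,linear_svm,0
abs_sel_vs_all,binary,decision_tree,3.4
abs_sel_vs_all,binary,ensemble_bagged_tree,3.4
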