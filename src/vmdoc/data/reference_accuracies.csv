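task,approach,features,classifier,accuracy,precision,recall,f1
binary,raw,all,knn,56.7,45,55,49.5
binary,raw,all,linear_svm,73.3,65.8,72.5,69
binary,raw,all,decision_tree,53.3,47.5,52.5,49.9
binary,raw,all,ensemble_bagged_tree,60,55.8,62.5,59
multiclass,raw,all,knn,46,37.2,48.3,42
multiclass,raw,all,linear_svm,35.5,28.3,40,33.1
multiclass,raw,all,decision_tree,40,31.8,41.7,36.1
multiclass,raw,all,ensemble_bagged_tree,45.5,40.7,48.3,44.2
binary,bands,all,knn,36.7,35.8,42.5,38.5
binary,bands,all,linear_svm,66.7,58.3,75,65.6
binary,bands,all,decision_tree,30,26.7,30,28.3
binary,bands,all,ensemble_bagged_tree,36.7,25.8,37.5,30.6
multiclass,bands,all,knn,34.5,32.5,35,33.7
multiclass,bands,all,linear_svm,45,36.1,41.7,38.7
multiclass,bands,all,decision_tree,43.5,36.1,43.3,39.4
multiclass,bands,all,ensemble_bagged_tree,42.5,34.2,45,38.9
binary,vmd,all,knn,60,44.2,57.5,50
binary,vmd,all,linear_svm,80,77.5,82.5,79.9
binary,vmd,all,decision_tree,63.3,62.5,67.5,64.9
binary,vmd,all,ensemble_bagged_tree,83.3,84.2,87.5,85.8
multiclass,vmd,all,knn,46,32.3,45,37.6
multiclass,vmd,all,linear_svm,57,46.9,56.7,51.3
multiclass,vmd,all,decision_tree,73.5,67.2,73.3,70.1
multiclass,vmd,all,ensemble_bagged_tree,76,78.9,78.3,78.6
binary,raw,selected,knn,56.7,52.5,57.5,54.9
binary,raw,selected,linear_svm,50,49.2,52.5,50.8
binary,raw,selected,decision_tree,43.3,40.8,47.5,43.9
binary,raw,selected,ensemble_bagged_tree,53.3,50,60,54.5
binary,bands,selected,knn,70,67.5,67.5,67.5
binary,bands,selected,linear_svm,46.7,35.8,47.5,40.8
binary,bands,selected,decision_tree,56.7,39.2,47.5,43
binary,bands,selected,ensemble_bagged_tree,76.7,70.8,77.5,74
binary,vmd,selected,knn,73.3,60.8,72.5,66.1
binary,vmd,selected,linear_svm,80,68.3,75,71.5
binary,vmd,selected,decision_tree,66.7,63.3,65,64.1
binary,vmd,selected,ensemble_bagged_tree,86.7,83.3,85,84.1
multiclass,raw,selected,knn,44,37.2,45,40.7
multiclass,raw,selected,linear_svm,32.5,21.6,36.7,27.2
multiclass,raw,selected,decision_tree,55,50.3,56.7,53.3
multiclass,raw,selected,ensemble_bagged_tree,50,45.3,51.7,48.3
multiclass,bands,selected,knn,42,33.9,45,38.7
multiclass,bands,selected,linear_svm,49,38,53.3,44.4
multiclass,bands,selected,decision_tree,52,42.8,55,48.1
multiclass,bands,selected,ensemble_bagged_tree,53.5,44.7,56.7,50
multiclass,vmd,selected,knn,61,53.1,58.3,55.6
multiclass,vmd,selected,linear_svm,70.5,67.8,75,71.2
multiclass,vmd,selected,decision_tree,57.5,50,58.3,53.8
multiclass,vmd,selected,ensemble_bagged_tree,80.5,81.1,81.7,81.4
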