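# synthetic selfcheck reference: mean thresholded varExpl maps of the
# five example models on the packaged deterministic synthetic fixture
l2_lr,pca_lr,nn_1layer,nn_5layer,nn_5layer_dense
0.7698119802408058,0.15596044519873697,0.7667074308070142,0.7665920567973391,0.7560249365301287
0.7806555820372019,0.032849863898181675,0.7770108555836021,0.7755400176635726,0.7697198411741168
0.7646787443200193,0.2450758720658337,0.7606831464918072,0.7627221938942661,0.7607278309733654
0.770487884468232,0.0,0.7715103211058697,0.7723749173342686,0.7673265949998651
0.7801875407525533,0.40242225061440706,0.7761887317382815,0.7789199677533322,0.7710099082749838
0.7802400448823595,0.2030043682087642,0.7769198700824606,0.7790959814806092,0.7719949987730906
0.8064055696121585,0.37238924812712854,0.8081106824351453,0.8073996057631495,0.7948544052042316
0.7825892376041562,0.24462780590315025,0.7824937330028691,0.7786996941762897,0.7617854368769222
0.7725766485141755,0.19930375197465902,0.7682843744737009,0.7684114114585804,0.7524613058575307
0.7763999133990899,0.28668454080364064,0.7723071886199716,0.7667967311614703,0.770783491842117
0.7744430540627502,0.11258461571048273,0.7713998815802766,0.7630303676317204,0.752368187187321
0.7709121181634951,0.13515915884687676,0.7699179655396614,0.7701518746899021,0.7592197972693305
0.7378607672727094,0.27928039642860614,0.7350408554744973,0.7330329105634386,0.7323360572355759
0.7510981740842704,0.3682748158860218,0.7439425404065446,0.7391815245946929,0.7314714999386975
0.7818062290981102,0.22006702386827,0.7801220401025036,0.7823680949782071,0.773348866726462
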