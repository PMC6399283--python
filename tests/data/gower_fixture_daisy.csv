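"1","2","3","4","5","6","7","8","9","10","11","12","13","14","15"
"0.000000000000000000","0.696840659340659307","0.510622710622710585","0.356181318681318637","0.788901098901098941","0.413736263736263710","0.757692307692307665","0.654807692307692202","0.187912087912087883","0.177106227106227060","0.767994505494505542","0.560714285714285721","0.647252747252747174","0.699999999999999845","0.420467032967032917"
"0.696840659340659307","0.000000000000000000","0.418498168498168621","0.810989010989010994","0.425824175824175921","0.381181318681318770","0.263186813186813195","0.615109890109890145","0.580631868131868178","0.564010989010989006","0.094871794871794826","0.691098901098901042","0.296886446886446997","0.619597069597069616","0.719560439560439691"
"0.510622710622710585","0.418498168498168621","0.000000000000000000","0.699862637362637319","0.651236263736263865","0.655769230769230882","0.563736263736263843","0.519597069597069638","0.408058608058608108","0.371611721611721624","0.513369963369963433","0.677747252747252782","0.545054945054945117","0.380219780219780201","0.585576923076923106"
"0.356181318681318637","0.810989010989010994","0.699862637362637319","0.000000000000000000","0.513186813186813140","0.584505494505494605","0.847362637362637394","0.471703296703296693","0.436675824175824179","0.449725274725274793","0.867912087912088070","0.377609890109890156","0.632857142857142896","0.668818681318681274","0.114285714285714310"
"0.788901098901098941","0.425824175824175921","0.651236263736263865","0.513186813186813140","0.000000000000000000","0.645604395604395753","0.417719780219780346","0.540934065934066122","0.676153846153846216","0.698021978021978073","0.443406593406593497","0.600329670329670551","0.350412087912087888","0.538873626373626236","0.452527472527472496"
"0.413736263736263710","0.381181318681318770","0.655769230769230882","0.584505494505494605","0.645604395604395753","0.000000000000000000","0.578571428571428625","0.612857142857142878","0.461813186813186893","0.434478021978022044","0.385027472527472492","0.517582417582417520","0.468131868131868245","0.845879120879120983","0.593076923076923057"
"0.757692307692307665","0.263186813186813195","0.563736263736263843","0.847362637362637394","0.417719780219780346","0.578571428571428625","0.000000000000000000","0.812500000000000000","0.622527472527472647","0.644093406593406526","0.258058608058608197","0.817582417582417564","0.357509157509157571","0.523076923076923106","0.755934065934065980"
"0.654807692307692202","0.615109890109890145","0.519597069597069638","0.471703296703296693","0.540934065934066122","0.612857142857142878","0.812500000000000000","0.000000000000000000","0.695741758241758212","0.668406593406593474","0.618956043956043978","0.405906593406593408","0.702060439560439620","0.773076923076923106","0.475274725274725307"
"0.187912087912087883","0.580631868131868178","0.408058608058608108","0.436675824175824179","0.676153846153846216","0.461813186813186893","0.622527472527472647","0.695741758241758212","0.000000000000000000","0.036446886446886428","0.648214285714285743","0.440934065934065977","0.645604395604395531","0.512087912087912045","0.322390109890109855"
"0.177106227106227060","0.564010989010989006","0.371611721611721624","0.449725274725274793","0.698021978021978073","0.434478021978022044","0.644093406593406526","0.668406593406593474","0.036446886446886428","0.000000000000000000","0.635164835164835129","0.427884615384615419","0.658653846153846145","0.548534798534798473","0.335439560439560469"
"0.767994505494505542","0.094871794871794826","0.513369963369963433","0.867912087912088070","0.443406593406593497","0.385027472527472492","0.258058608058608197","0.618956043956043978","0.648214285714285743","0.635164835164835129","0.000000000000000000","0.662747252747252658","0.391758241758241865","0.614468864468864506","0.776483516483516545"
"0.560714285714285721","0.691098901098901042","0.677747252747252782","0.377609890109890156","0.600329670329670551","0.517582417582417520","0.817582417582417564","0.405906593406593408","0.440934065934065977","0.427884615384615419","0.662747252747252658","0.000000000000000000","0.869230769230769362","0.789285714285714368","0.263324175824175832"
"0.647252747252747174","0.296886446886446997","0.545054945054945117","0.632857142857142896","0.350412087912087888","0.468131868131868245","0.357509157509157571","0.702060439560439620","0.645604395604395531","0.658653846153846145","0.391758241758241865","0.869230769230769362","0.000000000000000000","0.503663003663003650","0.658571428571428585"
"0.699999999999999845","0.619597069597069616","0.380219780219780201","0.668818681318681274","0.538873626373626236","0.845879120879120983","0.523076923076923106","0.773076923076923106","0.512087912087912045","0.548534798534798473","0.614468864468864506","0.789285714285714368","0.503663003663003650","0.000000000000000000","0.604532967032967106"
"0.420467032967032917","0.719560439560439691","0.585576923076923106","0.114285714285714310","0.452527472527472496","0.593076923076923057","0.755934065934065980","0.475274725274725307","0.322390109890109855","0.335439560439560469","0.776483516483516545","0.263324175824175832","0.658571428571428585","0.604532967032967106","0.000000000000000000"
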