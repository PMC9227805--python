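student_id,occasion_id,occasion_order,food_id,amount_g
S000001,S000001-d1-o1,1,beans_carioca,277.4
S000001,S000001-d1-o1,1,mango,12.3
S000001,S000001-d1-o1,1,pao_de_queijo,6.4
S000001,S000001-d1-o1,1,rice_brown,132.1
S000001,S000001-d1-o2,2,chicken_grilled,102.7
S000001,S000001-d1-o2,2,honey,16.7
S000001,S000001-d1-o2,2,lentils,312.8
S000001,S000001-d1-o3,3,acai_pulp,25.1
S000001,S000001-d1-o3,3,candy_hard,7.9
S000001,S000001-d1-o4,4,banana,33.0
S000001,S000001-d1-o4,4,beef_grilled,124.2
S000001,S000001-d1-o4,4,bread_whole,78.8
S000001,S000001-d1-o4,4,cassava_boiled,138.2
S000002,S000002-d1-o1,1,bread_whole,55.8
S000002,S000002-d1-o1,1,guarana_soda,48.5
S000002,S000002-d1-o1,1,soda_cola,24.5
S000002,S000002-d1-o1,1,soda_cola,185.2
S000002,S000002-d1-o2,2,chicken_grilled,81.8
S000002,S000002-d1-o2,2,salgado_fried,77.5
S000002,S000002-d1-o2,2,soda_cola,134.2
S000002,S000002-d1-o2,2,sugar_table,61.4
S000002,S000002-d1-o3,3,crackers_salt,66.0
S000002,S000002-d1-o4,4,corn_meal,274.8
S000002,S000002-d1-o4,4,couscous_corn,284.4
S000002,S000002-d1-o4,4,liver_beef,151.0
S000003,S000003-d1-o1,1,mango,87.7
S000003,S000003-d1-o1,1,papaya,262.0
S000003,S000003-d1-o1,1,salgado_fried,18.3
S000003,S000003-d1-o1,1,watermelon,261.6
S000003,S000003-d1-o2,2,chicken_grilled,174.6
S000003,S000003-d1-o2,2,guarana_soda,388.2
S000003,S000003-d1-o2,2,popcorn,141.7
S000003,S000003-d1-o3,3,chicken_grilled,167.5
S000003,S000003-d1-o3,3,lentils,370.1
S000003,S000003-d1-o3,3,salgado_fried,121.5
S000004,S000004-d1-o1,1,cake_plain,9.6
S000004,S000004-d1-o1,1,couscous_corn,125.7
S000004,S000004-d1-o2,2,pasta_cooked,76.6
S000004,S000004-d1-o3,3,couscous_corn,49.8
S000004,S000004-d1-o3,3,couscous_corn,125.7
S000004,S000004-d1-o3,3,honey,18.1
S000004,S000004-d1-o4,4,doce_leite,19.6
S000004,S000004-d1-o4,4,honey,10.7
S000004,S000004-d1-o5,5,acai_pulp,13.3
S000004,S000004-d1-o5,5,beef_grilled,159.2
S000004,S000004-d1-o5,5,cake_plain,30.6
S000004,S000004-d1-o5,5,couscous_corn,36.2
S000004,S000004-d1-o5,5,mango,135.1
S000004,S000004-d1-o6,6,bread_french,26.4
S000004,S000004-d1-o6,6,potato_boiled,105.9
S000005,S000005-d1-o1,1,chips_potato,28.1
S000005,S000005-d1-o1,1,cookies_sweet,13.6
S000005,S000005-d1-o1,1,pizza_slice,100.0
S000005,S000005-d1-o2,2,pasta_cooked,103.4
S000005,S000005-d1-o3,3,acaraje,97.2
S000005,S000005-d1-o3,3,liver_beef,75.5
S000005,S000005-d1-o3,3,popcorn,74.5
S000005,S000005-d1-o4,4,banana,108.7
S000005,S000005-d1-o4,4,cassava_flour,10.1
S000005,S000005-d1-o5,5,chicken_grilled,102.6
S000005,S000005-d1-o5,5,cookies_sweet,36.6
S000005,S000005-d1-o5,5,couscous_corn,222.4
S000006,S000006-d1-o1,1,guarana_soda,376.0
S000006,S000006-d1-o1,1,hamburger_bun,116.4
S000006,S000006-d1-o1,1,papaya,64.5
S000006,S000006-d1-o2,2,acaraje,157.1
S000006,S000006-d1-o2,2,cassava_boiled,176.7
S000006,S000006-d1-o2,2,guarana_soda,335.4
S000006,S000006-d1-o3,3,popcorn,68.8
S000006,S000006-d1-o3,3,soda_diet,350.0
S000006,S000006-d1-o4,4,apple,159.5
S000006,S000006-d1-o4,4,chicken_grilled,113.8
S000006,S000006-d1-o4,4,couscous_corn,52.7
S000006,S000006-d1-o4,4,ice_cream,122.5
S000006,S000006-d1-o4,4,orange_juice,118.8
S000007,S000007-d1-o1,1,cake_plain,34.3
S000007,S000007-d1-o1,1,watermelon,684.8
S000007,S000007-d1-o2,2,beef_grilled,97.3
S000007,S000007-d1-o2,2,corn_meal,199.6
S000007,S000007-d1-o2,2,doce_leite,26.9
S000007,S000007-d1-o2,2,orange_juice,85.0
S000007,S000007-d1-o2,2,papaya,208.8
S000007,S000007-d1-o3,3,pasta_cooked,158.7
S000007,S000007-d1-o4,4,corn_meal,291.3
S000007,S000007-d1-o4,4,pizza_slice,103.2
S000007,S000007-d1-o4,4,sausage_pork,169.3
S000007,S000007-d1-o4,4,tapioca,26.3
S000008,S000008-d1-o1,1,brigadeiro,10.4
S000008,S000008-d1-o1,1,hamburger_bun,36.8
S000008,S000008-d1-o1,1,sugar_table,36.0
S000008,S000008-d1-o2,2,acai_pulp,51.3
S000008,S000008-d1-o2,2,bread_whole,37.4
S000008,S000008-d1-o2,2,chicken_grilled,136.5
S000008,S000008-d1-o2,2,honey,38.4
S000008,S000008-d1-o2,2,mango,237.8
S000008,S000008-d1-o3,3,candy_hard,34.9
S000008,S000008-d1-o3,3,doce_leite,35.8
S000008,S000008-d1-o3,3,liver_beef,129.1
S000008,S000008-d1-o3,3,pao_de_queijo,156.6
S000009,S000009-d1-o1,1,cake_plain,14.2
S000009,S000009-d1-o1,1,cookies_sweet,28.0
S000009,S000009-d1-o1,1,hamburger_bun,10.6
S000009,S000009-d1-o1,1,mango,398.4
S000009,S000009-d1-o2,2,cookies_sweet,73.4
S000009,S000009-d1-o2,2,crackers_salt,8.0
S000009,S000009-d1-o2,2,soda_diet,350.0
S000009,S000009-d1-o3,3,crackers_salt,26.5
S000009,S000009-d1-o3,3,liver_beef,147.1
S000009,S000009-d1-o3,3,popcorn,22.8
S000009,S000009-d1-o3,3,rice_white,378.1
S000009,S000009-d1-o4,4,chips_potato,44.3
S000009,S000009-d1-o4,4,rice_white,126.2
S000009,S000009-d1-o5,5,pizza_slice,41.4
S000009,S000009-d1-o5,5,rice_brown,218.6
S000009,S000009-d1-o5,5,salgado_fried,30.5
S000009,S000009-d1-o5,5,sugar_table,6.1
S000010,S000010-d1-o1,1,acaraje,71.7
S000010,S000010-d1-o1,1,bread_whole,18.4
S000010,S000010-d1-o1,1,couscous_corn,126.4
S000010,S000010-d1-o1,1,crackers_salt,12.2
S000010,S000010-d1-o2,2,acai_pulp,76.1
S000010,S000010-d1-o2,2,acai_pulp,29.6
S000010,S000010-d1-o2,2,mango,131.0
S000010,S000010-d1-o3,3,acai_pulp,43.2
S000010,S000010-d1-o3,3,cassava_flour,20.3
S000010,S000010-d1-o3,3,soda_diet,350.0
S000010,S000010-d1-o4,4,bread_whole,133.5
S000010,S000010-d1-o4,4,sausage_pork,96.7
S000010,S000010-d1-o4,4,soda_cola,162.1
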