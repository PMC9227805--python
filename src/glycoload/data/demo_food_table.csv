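food_id,name,total_carb_g,fiber_g,gi,gi_source,similar_food_id,zero_class,protein_g,lipid_g
rice_white,white rice cooked,28.1,1.6,64,direct,,,2.5,0.2
rice_brown,brown rice cooked,25.8,2.7,55,direct,,,2.6,1.0
beans_black,black beans cooked,14.0,8.4,30,direct,,,4.5,0.5
beans_carioca,carioca beans cooked,13.6,8.5,29,direct,,,4.8,0.5
lentils,lentils cooked,16.3,7.9,32,direct,,,6.3,0.5
cassava_boiled,boiled cassava,30.1,1.6,46,direct,,,0.6,0.3
cassava_flour,toasted cassava flour,87.9,6.4,71,direct,,,1.6,0.3
potato_boiled,boiled potato,11.9,1.3,78,direct,,,1.2,0.1
corn_meal,corn meal polenta,22.3,2.4,68,direct,,,1.6,0.4
pasta_cooked,spaghetti cooked,30.9,1.9,49,direct,,,5.8,0.8
bread_french,french roll,58.6,2.3,75,direct,,,8.0,3.1
bread_whole,whole-grain bread,49.9,6.9,53,direct,,,9.4,3.7
crackers_salt,salted crackers,68.7,2.5,74,direct,,,10.1,14.0
cookies_sweet,sweet biscuits,75.2,1.7,77,direct,,,8.1,12.0
cake_plain,plain cake,57.9,0.8,67,direct,,,6.2,12.4
tapioca,tapioca crepe,88.0,0.4,93,literature,,,0.1,0.2
couscous_corn,corn couscous,25.3,2.1,65,literature,,,2.2,0.7
acai_pulp,acai pulp sweetened,52.2,2.6,62,literature,,,0.8,3.9
milk_whole,whole milk,4.7,0.0,39,direct,,,3.1,3.2
yogurt_sweet,sweetened yogurt,13.9,0.0,41,direct,,,3.5,2.9
cheese_minas,minas cheese,3.2,0.0,27,direct,,,17.4,20.2
banana,banana,23.8,1.9,51,direct,,,1.3,0.1
apple,apple,15.2,2.1,36,direct,,,0.3,0.2
orange,orange,11.7,4.0,43,direct,,,1.0,0.1
papaya,papaya,10.4,1.0,59,direct,,,0.5,0.1
mango,mango,16.7,1.6,51,direct,,,0.4,0.2
watermelon,watermelon,8.1,0.1,76,direct,,,0.9,0.2
orange_juice,orange juice,10.4,0.4,50,direct,,,0.7,0.1
soda_cola,sugar-sweetened cola,10.5,0.0,63,direct,,,0.0,0.0
guarana_soda,guarana soft drink,10.0,0.0,64,direct,,,0.0,0.0
sugar_table,table sugar,99.5,0.0,65,direct,,,0.0,0.0
honey,honey,84.0,0.4,61,direct,,,0.4,0.0
chocolate_bar,milk chocolate bar,59.6,2.2,43,direct,,,7.3,30.3
candy_hard,hard candy,97.8,0.0,78,direct,,,0.0,0.2
ice_cream,ice cream,23.0,0.7,51,direct,,,3.6,11.0
doce_leite,dulce de leche,57.0,0.0,47,literature,,,6.8,7.0
brigadeiro,chocolate fudge ball,65.3,1.9,,,doce_leite,,5.2,9.1
pao_de_queijo,cheese bread,34.2,0.5,,,bread_french,,5.1,12.3
acaraje,black-eyed-pea fritter,19.1,6.2,,,lentils,,8.3,15.7
chips_potato,potato chips,50.8,4.4,57,direct,,,5.6,34.6
popcorn,salted popcorn,57.2,10.0,65,direct,,,9.9,15.9
pizza_slice,cheese pizza,33.0,2.3,60,direct,,,10.9,10.1
hamburger_bun,hamburger sandwich,30.5,1.6,66,direct,,,13.0,12.6
salgado_fried,fried savory pastry,38.9,1.4,70,direct,,,8.6,17.1
egg_fried,fried egg,0.6,0.0,0,direct,,,15.6,18.6
lettuce_salad,lettuce and tomato salad,2.9,1.3,15,direct,,,1.2,0.2
beef_grilled,grilled beef,0.0,0.0,,,,meat_offal_sausage,32.0,10.9
chicken_grilled,grilled chicken,0.0,0.0,,,,meat_offal_sausage,32.0,7.5
sausage_pork,pork sausage,1.9,0.0,,,,meat_offal_sausage,15.4,28.4
liver_beef,beef liver,4.6,0.0,,,,meat_offal_sausage,29.9,5.7
soda_diet,diet carbonated beverage,0.0,0.0,,,,diet_beverage,0.0,0.0
cachaca,sugar-cane spirit,0.0,0.0,,,,distilled_spirit,0.0,0.0
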